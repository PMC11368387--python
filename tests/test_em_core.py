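"""Unit tests of the per-iteration EM computations against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from lucidpy import (
    LucidParams,
    i_step_impute,
    m_step_beta,
    m_step_gaussian_z,
    m_step_outcome,
    observed_loglik,
    responsibilities_complete,
    responsibilities_listwise,
    softmax_probs,
)
from lucidpy.datamodel import classify_missing_pattern

from _oracles import (
    gaussian_conditional_mean,
    naive_complete_loglik,
    naive_responsibilities,
    naive_responsibilities_listwise,
    newton_binary_logit,
    weighted_moments,
)


def _scalar_params(K=2, p=1, m=1):
    """Small hand-checkable parameter set."""
    beta = np.zeros((K, p + 1))
    if K == 2:
        beta[1] = np.linspace(0.2, -0.4, p + 1)
    mu = np.linspace(-1, 1, K)[:, None] * np.ones((K, m))
    Sigma = np.repeat((0.8 * np.eye(m))[None], K, axis=0)
    gamma = np.linspace(-0.5, 0.5, K)
    sigma2 = np.full(K, 1.3)
    return LucidParams(beta=beta, mu=mu, Sigma=Sigma, gamma=gamma, sigma2=sigma2)


class TestSoftmax:
    def test_zero_beta_is_uniform(self):
        G = np.random.default_rng(0).standard_normal((7, 3))
        S = softmax_probs(G, np.zeros((3, 4)))
        assert np.allclose(S, 1 / 3)

    def test_log_two_odds(self):
        beta = np.array([[0.0, 0.0], [0.0, np.log(2.0)]])
        S = softmax_probs(np.array([[1.0]]), beta)
        assert np.allclose(S, [[1 / 3, 2 / 3]])

    def test_matches_naive_exponentiation(self):
        rng = np.random.default_rng(1)
        G = rng.standard_normal((20, 3))
        beta = np.vstack([np.zeros(4), rng.normal(scale=0.5, size=(2, 4))])
        X = np.column_stack([np.ones(20), G])
        eta = X @ beta.T
        expected = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        assert np.allclose(softmax_probs(G, beta), expected, atol=1e-12)

    def test_nonzero_reference_row_rejected(self):
        with pytest.raises(ValueError):
            LucidParams(
                beta=np.ones((2, 2)), mu=np.zeros((2, 1)),
                Sigma=np.repeat(np.eye(1)[None], 2, 0),
                gamma=np.zeros(2), sigma2=np.ones(2),
            )


class TestResponsibilities:
    def test_single_cluster_is_one(self):
        params = _scalar_params(K=1)
        rng = np.random.default_rng(2)
        r = responsibilities_complete(
            rng.standard_normal((5, 1)), rng.standard_normal((5, 1)), rng.standard_normal(5), params
        )
        assert np.allclose(r, 1.0)

    def test_indistinguishable_clusters_uniform(self):
        K = 3
        params = LucidParams(
            beta=np.zeros((K, 2)), mu=np.zeros((K, 2)),
            Sigma=np.repeat(np.eye(2)[None], K, 0),
            gamma=np.zeros(K), sigma2=np.ones(K),
        )
        rng = np.random.default_rng(3)
        r = responsibilities_complete(
            rng.standard_normal((6, 1)), rng.standard_normal((6, 2)), rng.standard_normal(6), params
        )
        assert np.allclose(r, 1 / K)

    def test_matches_scalar_bayes_rule(self):
        params = _scalar_params()
        rng = np.random.default_rng(4)
        G = rng.standard_normal((10, 1))
        Z = rng.standard_normal((10, 1))
        Y = rng.standard_normal(10)
        assert np.allclose(
            responsibilities_complete(G, Z, Y, params),
            naive_responsibilities(G, Z, Y, params),
            atol=1e-10,
        )

    def test_listwise_drops_z_term(self):
        params = _scalar_params()
        rng = np.random.default_rng(5)
        G = rng.standard_normal((10, 1))
        Y = rng.standard_normal(10)
        assert np.allclose(
            responsibilities_listwise(G, Y, params),
            naive_responsibilities_listwise(G, Y, params),
            atol=1e-10,
        )

    def test_listwise_equal_outcome_params_reduces_to_softmax(self):
        params = _scalar_params()
        params.gamma = np.zeros(2)
        params.sigma2 = np.ones(2)
        rng = np.random.default_rng(6)
        G = rng.standard_normal((8, 1))
        r = responsibilities_listwise(G, rng.standard_normal(8), params)
        assert np.allclose(r, softmax_probs(G, params.beta), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        params = _scalar_params(K=3, p=2, m=2)
        params.beta = np.vstack([np.zeros(3), rng.normal(scale=2, size=(2, 3))])
        r = responsibilities_complete(
            rng.standard_normal((12, 2)), rng.standard_normal((12, 2)), rng.standard_normal(12), params
        )
        assert np.allclose(r.sum(axis=1), 1.0, atol=1e-10)
        assert (r >= 0).all() and (r <= 1).all()


class TestMStepBeta:
    def test_intercept_only_closed_form(self):
        n = 200
        r = np.column_stack([np.full(n, 0.75), np.full(n, 0.25)])
        G = np.zeros((n, 0))  # no covariates
        beta = m_step_beta(G, r)
        assert beta[1, 0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)

    def test_uniform_responsibilities_give_zero_beta(self):
        rng = np.random.default_rng(7)
        G = rng.standard_normal((50, 3))
        r = np.full((50, 2), 0.5)
        assert np.abs(m_step_beta(G, r)).max() < 1e-6

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(8)
        G = rng.standard_normal((100, 2))
        logits = G @ [0.8, -0.5]
        r1 = 1 / (1 + np.exp(-logits))
        r = np.column_stack([1 - r1, r1])
        beta = m_step_beta(G, r, gtol=1e-10)
        expected = newton_binary_logit(G, r)
        assert np.allclose(beta, expected, atol=1e-6)

    def test_hard_labels_nonseparating(self):
        rng = np.random.default_rng(9)
        G = rng.standard_normal((80, 1))
        labels = rng.integers(0, 2, 80)
        r = np.column_stack([1 - labels, labels]).astype(float)
        beta = m_step_beta(G, r, gtol=1e-10)
        expected = newton_binary_logit(G, r)
        assert np.allclose(beta, expected, atol=1e-6)


class TestMStepGaussianZ:
    def test_single_cluster_reduces_to_sample_moments(self):
        rng = np.random.default_rng(10)
        Z = rng.standard_normal((30, 3))
        r = np.ones((30, 1))
        mu, Sigma = m_step_gaussian_z(Z, r, "VVV")
        assert np.allclose(mu[0], Z.mean(axis=0))
        expected = np.cov(Z, rowvar=False, bias=True)  # ML denominator n
        assert np.allclose(Sigma[0], expected, atol=1e-5)

    def test_eii_matches_scalar_formula(self):
        rng = np.random.default_rng(11)
        Z = rng.standard_normal((40, 2))
        r = rng.dirichlet(np.ones(2), size=40)
        mu, Sigma = m_step_gaussian_z(Z, r, "EII")
        lam_expected = sum(
            np.sum(r[:, j] * ((Z - mu[j]) ** 2).sum(axis=1)) for j in range(2)
        ) / (40 * 2)
        for j in range(2):
            off = Sigma[j] - np.diag(np.diag(Sigma[j]))
            assert np.allclose(off, 0)
            assert np.allclose(np.diag(Sigma[j]), lam_expected, rtol=1e-4)
        assert np.allclose(Sigma[0], Sigma[1])

    def test_m1_matches_numeric_q_maximizer(self):
        rng = np.random.default_rng(12)
        Z = rng.standard_normal((25, 1)) + 0.5
        r = rng.dirichlet(np.ones(2), size=25)
        mu, Sigma = m_step_gaussian_z(Z, r, "VVV")

        def neg_q(x, j):
            mj, log_s = x
            s2 = np.exp(log_s)
            return -np.sum(r[:, j] * (-0.5 * np.log(2 * np.pi * s2) - (Z[:, 0] - mj) ** 2 / (2 * s2)))

        for j in range(2):
            res = optimize.minimize(neg_q, [0.0, 0.0], args=(j,), method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12})
            assert mu[j, 0] == pytest.approx(res.x[0], abs=1e-4)
            assert Sigma[j, 0, 0] == pytest.approx(np.exp(res.x[1]), rel=1e-3)

    def test_constrained_families_shapes(self):
        rng = np.random.default_rng(13)
        Z = rng.standard_normal((30, 3))
        r = rng.dirichlet(np.ones(2), size=30)
        _, s_vii = m_step_gaussian_z(Z, r, "VII")
        _, s_eee = m_step_gaussian_z(Z, r, "EEE")
        assert np.allclose(s_vii[0], np.eye(3) * s_vii[0, 0, 0])
        assert not np.allclose(s_vii[0, 0, 0], s_vii[1, 0, 0])
        assert np.allclose(s_eee[0], s_eee[1])

    def test_degenerate_cluster_rejected(self):
        Z = np.random.default_rng(14).standard_normal((20, 2))
        r = np.column_stack([np.ones(20), np.zeros(20)])
        with pytest.raises(ValueError, match="degenerate"):
            m_step_gaussian_z(Z, r, "VVV")


class TestMStepOutcome:
    def test_hard_assignment_gives_per_cluster_moments(self):
        rng = np.random.default_rng(15)
        Y = rng.standard_normal(30)
        labels = np.repeat([0, 1], 15)
        r = np.column_stack([1 - labels, labels]).astype(float)
        gamma, sigma2 = m_step_outcome(Y, r)
        assert gamma[0] == pytest.approx(Y[:15].mean())
        assert sigma2[1] == pytest.approx(Y[15:].var())  # ML variance

    def test_uniform_r_gives_overall_mean(self):
        Y = np.random.default_rng(16).standard_normal(20)
        gamma, _ = m_step_outcome(Y, np.full((20, 3), 1 / 3))
        assert np.allclose(gamma, Y.mean())

    def test_matches_weighted_moment_oracle(self):
        rng = np.random.default_rng(17)
        Y = rng.standard_normal(10)
        r = rng.dirichlet(np.ones(2), size=10)
        gamma, sigma2 = m_step_outcome(Y, r)
        g_exp, s_exp = weighted_moments(Y, r)
        assert np.allclose(gamma, g_exp)
        assert np.allclose(sigma2, s_exp)


def _random_pd(rng, m):
    A = rng.standard_normal((m, m))
    return A @ A.T + 0.3 * np.eye(m)


class TestIStep:
    def test_k1_equals_conditional_mean(self):
        rng = np.random.default_rng(18)
        m = 4
        Sigma = _random_pd(rng, m)
        mu = rng.standard_normal(m)
        params = LucidParams(
            beta=np.zeros((1, 2)), mu=mu[None], Sigma=Sigma[None],
            gamma=np.zeros(1), sigma2=np.ones(1),
        )
        z = rng.standard_normal(m)
        miss = np.array([False, True, False, True])
        out = i_step_impute(z, miss, np.array([1.0]), params)
        expected = gaussian_conditional_mean(
            z[~miss], np.flatnonzero(~miss), np.flatnonzero(miss), mu, Sigma
        )
        assert np.allclose(out[miss], expected, atol=1e-8)
        assert np.array_equal(out[~miss], z[~miss])

    def test_fully_observed_row_is_noop(self):
        params = _scalar_params(m=2)
        z = np.array([0.3, -0.2])
        out = i_step_impute(z, np.zeros(2, dtype=bool), np.array([0.5, 0.5]), params)
        assert np.array_equal(out, z)

    def test_degenerate_weights_reduce_to_single_cluster(self):
        rng = np.random.default_rng(19)
        m = 2
        mu = np.array([[0.0, 0.0], [5.0, 5.0]])
        Sigma = np.array([_random_pd(rng, m), _random_pd(rng, m)])
        params = LucidParams(
            beta=np.zeros((2, 2)), mu=mu, Sigma=Sigma,
            gamma=np.zeros(2), sigma2=np.ones(2),
        )
        z = np.array([0.7, np.nan])
        miss = np.array([False, True])
        z_in = np.array([0.7, 0.0])
        out = i_step_impute(z_in, miss, np.array([1.0, 0.0]), params)
        expected = gaussian_conditional_mean(z_in[:1], [0], [1], mu[0], Sigma[0])
        assert out[1] == pytest.approx(expected[0], abs=1e-10)

    def test_fully_missing_row_rejected(self):
        params = _scalar_params(m=2)
        with pytest.raises(ValueError, match="fully missing"):
            i_step_impute(np.zeros(2), np.ones(2, dtype=bool), np.array([0.5, 0.5]), params)


class TestQAscent:
    def test_m_step_updates_weakly_increase_their_q_terms(self):
        """Each M-step block maximizes its own term of the expected
        complete-data log-likelihood, so the term cannot decrease."""
        rng = np.random.default_rng(30)
        n, p, m = 60, 2, 2
        G = rng.standard_normal((n, p))
        Z = rng.standard_normal((n, m))
        Y = rng.standard_normal(n)
        params = _scalar_params(K=2, p=p, m=m)
        r = responsibilities_complete(G, Z, Y, params)

        from lucidpy.em_core import log_softmax_probs, log_mvn_density

        def q_beta(beta):
            return float(np.sum(r * log_softmax_probs(G, beta)))

        def q_z(mu, Sigma):
            return float(sum(np.sum(r[:, j] * log_mvn_density(Z, mu[j], Sigma[j])) for j in range(2)))

        def q_y(gamma, sigma2):
            return float(sum(np.sum(
                r[:, j] * (-0.5 * (np.log(2 * np.pi * sigma2[j]) + (Y - gamma[j]) ** 2 / sigma2[j]))
            ) for j in range(2)))

        beta_new = m_step_beta(G, r, beta_init=params.beta)
        assert q_beta(beta_new) >= q_beta(params.beta) - 1e-10
        mu_new, Sigma_new = m_step_gaussian_z(Z, r, "VVV")
        assert q_z(mu_new, Sigma_new) >= q_z(params.mu, params.Sigma) - 1e-10
        gamma_new, sigma2_new = m_step_outcome(Y, r)
        assert q_y(gamma_new, sigma2_new) >= q_y(params.gamma, params.sigma2) - 1e-10


class TestObservedLoglik:
    def test_standard_normal_closed_form(self):
        params = LucidParams(
            beta=np.zeros((1, 2)), mu=np.zeros((1, 1)), Sigma=np.eye(1)[None],
            gamma=np.zeros(1), sigma2=np.ones(1),
        )
        from lucidpy import LucidData

        data = LucidData(G=np.zeros((2, 1)), Z=np.zeros((2, 1)), Y=np.zeros(2),
                         mask=np.zeros((2, 1), dtype=bool))
        part = classify_missing_pattern(data.mask)
        ll = observed_loglik(data.G, data.Z, data.Y, part, params)
        assert ll == pytest.approx(2 * 2 * (-0.5 * np.log(2 * np.pi)), abs=1e-12)

    def test_complete_data_matches_direct_summation(self, tiny_fixture):
        params = _scalar_params(K=2, p=2, m=2)
        part = classify_missing_pattern(tiny_fixture.mask)
        ll = observed_loglik(tiny_fixture.G, tiny_fixture.Z, tiny_fixture.Y, part, params)
        expected = naive_complete_loglik(tiny_fixture.G, tiny_fixture.Z, tiny_fixture.Y, params)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_listwise_rows_ignore_omics_parameters(self):
        rng = np.random.default_rng(20)
        params = _scalar_params(K=2, p=1, m=2)
        G = rng.standard_normal((6, 1))
        Z = rng.standard_normal((6, 2))
        Y = rng.standard_normal(6)
        mask = np.zeros((6, 2), dtype=bool)
        mask[4:] = True  # two fully missing rows
        Zc = Z.copy()
        Zc[4:] = np.nan
        part = classify_missing_pattern(mask)
        ll1 = observed_loglik(G, Zc, Y, part, params)
        perturbed = _scalar_params(K=2, p=1, m=2)
        perturbed.mu = params.mu + 2.0
        ll_full1 = observed_loglik(G[:4], Zc[:4], Y[:4], classify_missing_pattern(mask[:4]), params)
        ll_full2 = observed_loglik(G[:4], Zc[:4], Y[:4], classify_missing_pattern(mask[:4]), perturbed)
        ll2 = observed_loglik(G, Zc, Y, part, perturbed)
        # the ic contribution is unchanged by the mu shift
        assert ll1 - ll_full1 == pytest.approx(ll2 - ll_full2, abs=1e-10)
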