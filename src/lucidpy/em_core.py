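"""Per-iteration computations of the LUCID EM algorithm.

The model: latent cluster X with k categories; X | G multinomial through a
softmax with coefficients beta (reference cluster's row fixed at zero);
Z | X = j multivariate Gaussian N(mu_j, Sigma_j); Y | X = j univariate
Gaussian N(gamma_j, sigma2_j).  The complete-data log-likelihood separates
into the three components, so the M-step decouples: a responsibility-
weighted multinomial-logit fit for beta, weighted Gaussian moments for
(mu_j, Sigma_j) and (gamma_j, sigma2_j).

Rows whose Z is entirely missing drop the Z density from their posterior
(responsibilities_listwise) and from the observed-data likelihood; rows with
sporadically missing cells are carried at their current imputation, which an
I-step refreshes each iteration with the responsibility-weighted Gaussian
conditional mean (i_step_impute).

All probability work is done in log space with log-sum-exp normalization.
Covariance matrices may be constrained to one of four families from the
eigenvalue-decomposition parameterization Sigma_j = lambda_j D_j A_j D_j^T:
spherical shared (EII), spherical per-cluster (VII), full shared (EEE) and
full per-cluster (VVV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, optimize
from scipy.special import logsumexp

__all__ = [
    "CovarianceFamily",
    "LucidParams",
    "softmax_probs",
    "log_softmax_probs",
    "responsibilities_complete",
    "responsibilities_listwise",
    "m_step_beta",
    "m_step_gaussian_z",
    "m_step_outcome",
    "i_step_impute",
    "observed_loglik",
]

COV_FAMILIES = ("EII", "VII", "EEE", "VVV")

#: ridge scale applied to each Sigma_j (times its mean diagonal) so that
#: repeated inversions stay well-posed for near-degenerate clusters
RIDGE_SCALE = 1e-6
SIGMA2_FLOOR = 1e-8


class CovarianceFamily(str):
    """Covariance-family tag: one of EII, VII, EEE, VVV.

    EII: Sigma_j = lambda I shared; VII: Sigma_j = lambda_j I;
    EEE: one full Sigma shared across clusters; VVV: unconstrained per cluster.
    """

    def __new__(cls, tag: str):
        tag = str(tag).upper()
        if tag not in COV_FAMILIES:
            raise ValueError(f"unknown covariance family {tag!r}; choose from {COV_FAMILIES}")
        return super().__new__(cls, tag)


@dataclass
class LucidParams:
    """Full parameter set Theta of a K-cluster LUCID model.

    beta : (K, p+1) multinomial-logit coefficients, intercept first;
        the reference row (cluster 0) is identically zero.
    mu : (K, m) cluster means of Z.
    Sigma : (K, m, m) cluster covariances of Z, each symmetric PD.
    gamma : (K,) cluster means of Y.
    sigma2 : (K,) cluster variances of Y, strictly positive.
    """

    beta: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    gamma: np.ndarray
    sigma2: np.ndarray
    cov_model: str = "VVV"

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.ndim == 2:
            self.Sigma = self.Sigma[None, :, :]
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.cov_model = CovarianceFamily(self.cov_model)
        k = self.beta.shape[0]
        if not (self.mu.shape[0] == self.Sigma.shape[0] == self.gamma.shape[0] == self.sigma2.shape[0] == k):
            raise ValueError("inconsistent cluster counts across parameter blocks")
        if np.abs(self.beta[0]).max() > 1e-12:
            raise ValueError("reference-cluster row of beta must be zero")
        if (self.sigma2 <= 0).any():
            raise ValueError("sigma2 must be strictly positive")

    @property
    def K(self) -> int:
        return self.beta.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[1] - 1

    @property
    def m(self) -> int:
        return self.mu.shape[1]

    def relabel(self, order: np.ndarray) -> "LucidParams":
        """Permute cluster labels; the new reference is order[0].

        The softmax is invariant under subtracting one row of beta from all
        rows, which restores the zero reference after permutation.
        """
        order = np.asarray(order)
        beta = self.beta[order] - self.beta[order[0]]
        return replace(
            self,
            beta=beta,
            mu=self.mu[order].copy(),
            Sigma=self.Sigma[order].copy(),
            gamma=self.gamma[order].copy(),
            sigma2=self.sigma2[order].copy(),
        )


def _design(G: np.ndarray) -> np.ndarray:
    """Prepend the intercept column."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    return np.column_stack([np.ones(G.shape[0]), G])


def log_softmax_probs(G: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Row-wise log S(X=j | G; beta) via log-sum-exp."""
    eta = _design(G) @ np.asarray(beta, dtype=float).T
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor in softmax")
    return eta - logsumexp(eta, axis=1, keepdims=True)


def softmax_probs(G: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Cluster membership probabilities S(X=j | G; beta), rows summing to 1."""
    return np.exp(log_softmax_probs(G, beta))


def _chol_factor(Sigma: np.ndarray, j: int | None = None):
    try:
        return linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError as err:
        where = "" if j is None else f" for cluster {j}"
        raise ValueError(f"singular covariance matrix{where}") from err


def log_mvn_density(Z: np.ndarray, mu: np.ndarray, Sigma: np.ndarray, j: int | None = None) -> np.ndarray:
    """log N(Z_i | mu, Sigma) for each row of Z, via a Cholesky solve."""
    Z = np.atleast_2d(Z)
    m = Z.shape[1]
    L = _chol_factor(Sigma, j)
    dev = linalg.solve_triangular(L, (Z - mu).T, lower=True)
    maha = np.sum(dev * dev, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (m * np.log(2.0 * np.pi) + logdet + maha)


def _log_norm_density(Y: np.ndarray, gamma: float, sigma2: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * sigma2) + (Y - gamma) ** 2 / sigma2)


def _log_joint_complete(G, Z, Y, params: LucidParams) -> np.ndarray:
    """(n, K) matrix of log S + log phi(Z) + log phi(Y)."""
    log_s = log_softmax_probs(G, params.beta)
    out = np.empty_like(log_s)
    for j in range(params.K):
        out[:, j] = (
            log_s[:, j]
            + log_mvn_density(Z, params.mu[j], params.Sigma[j], j)
            + _log_norm_density(Y, params.gamma[j], params.sigma2[j])
        )
    return out


def _log_joint_listwise(G, Y, params: LucidParams) -> np.ndarray:
    """(n, K) matrix of log S + log phi(Y); the Z density is dropped."""
    log_s = log_softmax_probs(G, params.beta)
    out = np.empty_like(log_s)
    for j in range(params.K):
        out[:, j] = log_s[:, j] + _log_norm_density(Y, params.gamma[j], params.sigma2[j])
    return out


def _normalize_log(logw: np.ndarray) -> np.ndarray:
    r = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    return r / r.sum(axis=1, keepdims=True)


def responsibilities_complete(G, Z, Y, params: LucidParams) -> np.ndarray:
    """Posterior inclusion probabilities for rows with (currently) complete Z.

    r_ij proportional to S(X_i=j|G_i) * phi(Z_i|mu_j,Sigma_j) * phi(Y_i|gamma_j,sigma2_j),
    normalized over j in log space.  Rows with sporadically missing cells must
    be passed at their current imputation.
    """
    return _normalize_log(_log_joint_complete(G, Z, Y, params))


def responsibilities_listwise(G, Y, params: LucidParams) -> np.ndarray:
    """Posterior inclusion probabilities for rows whose Z is fully missing."""
    return _normalize_log(_log_joint_listwise(G, Y, params))


def _beta_negloglik(free: np.ndarray, X: np.ndarray, r: np.ndarray, K: int):
    """Weighted multinomial-logit negative log-likelihood and gradient.

    ``free`` holds rows 1..K-1 of beta; the reference row stays zero.
    """
    n, d = X.shape
    beta = np.zeros((K, d))
    beta[1:] = free.reshape(K - 1, d)
    eta = X @ beta.T
    lse = logsumexp(eta, axis=1, keepdims=True)
    log_p = eta - lse
    nll = -np.sum(r * log_p)
    P = np.exp(log_p)
    # gradient of -sum_ij r_ij log p_ij wrt beta_j (j >= 1): X^T (p_j - r_j)
    grad = ((P - r).T @ X)[1:]
    return nll, grad.ravel()


def m_step_beta(
    G: np.ndarray,
    r: np.ndarray,
    beta_init: np.ndarray | None = None,
    gtol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Maximize the responsibility-weighted multinomial log-likelihood.

    No closed form exists; L-BFGS with the analytic gradient is run to a
    gradient-norm tolerance.  On non-convergence the last iterate is returned
    with a warning rather than raising, since a slightly stale beta merely
    slows the outer EM loop.
    """
    X = _design(G)
    r = np.asarray(r, dtype=float)
    K = r.shape[1]
    d = X.shape[1]
    if K == 1:
        return np.zeros((1, d))
    if beta_init is None:
        x0 = np.zeros((K - 1) * d)
    else:
        x0 = np.asarray(beta_init, dtype=float)[1:].ravel().copy()
    res = optimize.minimize(
        _beta_negloglik,
        x0,
        args=(X, r, K),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        warnings.warn(
            f"multinomial-logit M-step did not converge: {res.message}",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = np.zeros((K, d))
    beta[1:] = res.x.reshape(K - 1, d)
    return beta


def _apply_ridge(Sigma: np.ndarray) -> np.ndarray:
    for j in range(Sigma.shape[0]):
        eps = RIDGE_SCALE * np.mean(np.diag(Sigma[j]))
        if eps <= 0:
            eps = RIDGE_SCALE
        Sigma[j] += eps * np.eye(Sigma.shape[1])
    return Sigma


def m_step_gaussian_z(
    Z: np.ndarray,
    r: np.ndarray,
    cov_model: str = "VVV",
    weight_floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-moment update of (mu_j, Sigma_j) under a covariance family.

    Only rows whose Z is observed or currently imputed may be passed; rows
    with fully missing Z carry no information about the omics parameters.

    mu_j is the responsibility-weighted mean.  Sigma_j is the weighted ML
    covariance (denominator sum of weights, not n-1), then projected onto
    the requested family:

    * VVV: per-cluster full matrix (unconstrained closed form);
    * EEE: the weight-pooled full matrix, shared;
    * VII: lambda_j I with lambda_j = weighted mean squared deviation / m;
    * EII: lambda I pooled across clusters, lambda = total weighted squared
      deviation / (n m).

    A small ridge proportional to the mean diagonal keeps each matrix PD.
    """
    cov_model = CovarianceFamily(cov_model)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    r = np.asarray(r, dtype=float)
    n, m = Z.shape
    K = r.shape[1]
    w = r.sum(axis=0)
    if weight_floor is None:
        weight_floor = 1e-6 * n
    if (w < weight_floor).any():
        bad = np.flatnonzero(w < weight_floor)
        raise ValueError(f"degenerate cluster(s) {bad.tolist()}: effective weight below {weight_floor:g}")
    mu = (r.T @ Z) / w[:, None]

    full = np.empty((K, m, m))
    for j in range(K):
        dev = Z - mu[j]
        full[j] = (dev * r[:, j : j + 1]).T @ dev / w[j]

    if cov_model == "VVV":
        Sigma = full
    elif cov_model == "EEE":
        pooled = np.einsum("j,jab->ab", w, full) / n
        Sigma = np.repeat(pooled[None], K, axis=0)
    elif cov_model == "VII":
        lam = np.array([np.trace(full[j]) / m for j in range(K)])
        Sigma = lam[:, None, None] * np.eye(m)[None]
    else:  # EII
        lam = float(np.einsum("j,j->", w, [np.trace(full[j]) for j in range(K)])) / (n * m)
        Sigma = np.repeat((lam * np.eye(m))[None], K, axis=0)
    return mu, _apply_ridge(Sigma)


def m_step_outcome(Y: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean and ML variance of Y per cluster (all rows contribute)."""
    Y = np.asarray(Y, dtype=float).ravel()
    r = np.asarray(r, dtype=float)
    w = r.sum(axis=0)
    gamma = (r.T @ Y) / w
    sigma2 = (r.T @ (Y[:, None] - gamma[None, :]) ** 2).diagonal().copy() / w
    # the paper's model has no variance floor; clip only to dodge exact zeros
    low = sigma2 < SIGMA2_FLOOR
    if low.any():
        warnings.warn(
            f"outcome variance clipped to {SIGMA2_FLOOR:g} for cluster(s) {np.flatnonzero(low).tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma2 = np.where(low, SIGMA2_FLOOR, sigma2)
    return gamma, sigma2


def i_step_impute(
    z_row: np.ndarray,
    miss: np.ndarray,
    r_row: np.ndarray,
    params: LucidParams,
) -> np.ndarray:
    """Refresh the missing cells of one sporadically missing row.

    The update solves, in closed form, the stationarity condition of the
    weighted Gaussian log-density with the observed block fixed.  With
    precision blocks Lambda_j = Sigma_j^{-1} partitioned by observed (a) /
    missing (b) coordinates,

        Z_b <- [sum_j w_j Lambda_j^{bb}]^{-1}
               sum_j w_j (Lambda_j^{ba} mu_a + Lambda_j^{bb} mu_b - Lambda_j^{ba} Z_a)

    where w_j = r_j * phi(Z_i | mu_j, Sigma_j), with phi evaluated at the
    row's current (previous-iteration) imputation.  ``r_row`` plays the role
    of the cluster weight *before* seeing Z — in the full fit the driver
    passes the Z-free responsibility (softmax times outcome density,
    normalized), so that w_j is the row's full posterior responsibility at
    the current parameters and the update is an exact minorize–maximize
    step: the mixture log-likelihood cannot decrease.  The weights are
    normalized over j before use — the solution is invariant to joint
    rescaling, and normalization prevents underflow.  If every weight
    underflows even in log space, the single cluster with the largest
    log-weight is used.

    At K=1 this reduces algebraically to the Gaussian conditional mean
    mu_b + Sigma_ba Sigma_aa^{-1} (Z_a - mu_a).
    """
    z_row = np.asarray(z_row, dtype=float).copy()
    miss = np.asarray(miss, dtype=bool)
    if not miss.any():
        return z_row
    if miss.all():
        raise ValueError("row is fully missing; handled by the likelihood partition, not the I-step")
    obs = ~miss
    K = params.K
    nb = int(miss.sum())

    logw = np.empty(K)
    for j in range(K):
        logw[j] = log_mvn_density(z_row[None, :], params.mu[j], params.Sigma[j], j)[0]
    with np.errstate(divide="ignore"):
        logw = logw + np.log(np.asarray(r_row, dtype=float))
    if not np.isfinite(logw).any():
        raise ValueError("all imputation weights are degenerate")
    shifted = logw - logw.max()
    w = np.exp(shifted)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):  # extreme underflow: keep the dominant cluster
        w = (shifted == 0).astype(float)
        total = w.sum()
    w = w / total

    A = np.zeros((nb, nb))
    b = np.zeros(nb)
    for j in range(K):
        if w[j] == 0.0:
            continue
        Lam = np.linalg.inv(params.Sigma[j])
        Lbb = Lam[np.ix_(miss, miss)]
        Lba = Lam[np.ix_(miss, obs)]
        mu_a = params.mu[j][obs]
        mu_b = params.mu[j][miss]
        A += w[j] * Lbb
        b += w[j] * (Lba @ mu_a + Lbb @ mu_b - Lba @ z_row[obs])
    z_row[miss] = np.linalg.solve(A, b)
    return z_row


def observed_loglik(
    G: np.ndarray,
    Z_current: np.ndarray,
    Y: np.ndarray,
    partition,
    params: LucidParams,
) -> float:
    """Partitioned observed-data log-likelihood.

    Rows with observed (or imputed) Z contribute
    log sum_j S * phi(Z) * phi(Y); fully missing rows contribute
    log sum_j S * phi(Y).  All mixtures via log-sum-exp.
    """
    total = 0.0
    iab = partition.iab
    if iab.size:
        lj = _log_joint_complete(G[iab], Z_current[iab], Y[iab], params)
        total += float(logsumexp(lj, axis=1).sum())
    if partition.ic.size:
        ic = partition.ic
        lj = _log_joint_listwise(G[ic], Y[ic], params)
        total += float(logsumexp(lj, axis=1).sum())
    if not np.isfinite(total):
        raise ValueError("non-finite log-likelihood; check for degenerate parameters")
    return total
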