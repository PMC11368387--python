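"""Independent brute-force references used by the tests.

Everything here deliberately avoids the package's log-space code paths:
densities come from scipy.stats, normalization is naive arithmetic, and the
multinomial-logit maximizer is a hand-coded Newton iteration (binary case)
or a derivative-free optimizer.  These stay small and slow on purpose.
"""

import numpy as np
from scipy import stats


def naive_responsibilities(G, Z, Y, params):
    """Bayes-rule posterior with naive (non-log) arithmetic."""
    n = G.shape[0]
    K = params.K
    X = np.column_stack([np.ones(n), G])
    eta = X @ params.beta.T
    S = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
    num = np.empty((n, K))
    for j in range(K):
        fz = stats.multivariate_normal.pdf(Z, mean=params.mu[j], cov=params.Sigma[j])
        fy = stats.norm.pdf(Y, loc=params.gamma[j], scale=np.sqrt(params.sigma2[j]))
        num[:, j] = S[:, j] * np.atleast_1d(fz) * fy
    return num / num.sum(axis=1, keepdims=True)


def naive_responsibilities_listwise(G, Y, params):
    n = G.shape[0]
    K = params.K
    X = np.column_stack([np.ones(n), G])
    eta = X @ params.beta.T
    S = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
    num = np.empty((n, K))
    for j in range(K):
        num[:, j] = S[:, j] * stats.norm.pdf(Y, loc=params.gamma[j], scale=np.sqrt(params.sigma2[j]))
    return num / num.sum(axis=1, keepdims=True)


def newton_binary_logit(G, r, tol=1e-12, max_iter=200):
    """Weighted binary-logit MLE by damped Newton (K=2, reference cluster 0).

    Maximizes sum_i r_i1 log p_i + r_i0 log(1-p_i) with p_i = sigmoid(x_i b).
    """
    n, p = G.shape
    X = np.column_stack([np.ones(n), G])
    b = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = X @ b
        prob = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (r[:, 1] - prob)
        W = prob * (1.0 - prob)
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        b = b + step
        if np.abs(grad).max() < tol:
            break
    beta = np.zeros((2, p + 1))
    beta[1] = b
    return beta


def weighted_moments(Y, r):
    """Spreadsheet-style per-cluster weighted mean and ML variance of Y."""
    K = r.shape[1]
    gamma = np.empty(K)
    sigma2 = np.empty(K)
    for j in range(K):
        w = r[:, j]
        gamma[j] = np.sum(w * Y) / np.sum(w)
        sigma2[j] = np.sum(w * (Y - gamma[j]) ** 2) / np.sum(w)
    return gamma, sigma2


def gaussian_conditional_mean(z_obs, obs_idx, miss_idx, mu, Sigma):
    """mu_b + Sigma_ba Sigma_aa^{-1} (z_a - mu_a) for one Gaussian."""
    Saa = Sigma[np.ix_(obs_idx, obs_idx)]
    Sba = Sigma[np.ix_(miss_idx, obs_idx)]
    return mu[miss_idx] + Sba @ np.linalg.solve(Saa, z_obs - mu[obs_idx])


def naive_complete_loglik(G, Z, Y, params):
    """Direct summation of the complete-data mixture log-likelihood."""
    n = G.shape[0]
    X = np.column_stack([np.ones(n), G])
    eta = X @ params.beta.T
    S = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
    total = 0.0
    for i in range(n):
        acc = 0.0
        for j in range(params.K):
            acc += (
                S[i, j]
                * stats.multivariate_normal.pdf(Z[i], mean=params.mu[j], cov=params.Sigma[j])
                * stats.norm.pdf(Y[i], loc=params.gamma[j], scale=np.sqrt(params.sigma2[j]))
            )
        total += np.log(acc)
    return total


def one_em_iteration(G, Z, Y, params, ridge_scale=1e-6):
    """One complete-data EM iteration (E-step then unconstrained M-step),
    written from the definitions with naive arithmetic.

    Mirrors the package's ridge so parameter values are directly comparable.
    """
    r = naive_responsibilities(G, Z, Y, params)
    K = params.K
    m = Z.shape[1]
    w = r.sum(axis=0)
    mu = np.empty((K, m))
    Sigma = np.empty((K, m, m))
    for j in range(K):
        mu[j] = (r[:, j : j + 1] * Z).sum(axis=0) / w[j]
        dev = Z - mu[j]
        Sigma[j] = (r[:, j : j + 1] * dev).T @ dev / w[j]
        Sigma[j] += ridge_scale * np.mean(np.diag(Sigma[j])) * np.eye(m)
    gamma, sigma2 = weighted_moments(Y, r)
    beta = newton_binary_logit(G, r) if K == 2 else None
    return r, beta, mu, Sigma, gamma, sigma2
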