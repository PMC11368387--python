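"""End-to-end model fitting: initialization, the E/M/I loop, convergence,
BIC-based selection of the number of clusters, and baseline fitters.

One outer iteration runs, in order:

1. E-step — responsibilities from the current parameters (full posterior for
   rows with observed/imputed Z, exposure-and-outcome posterior for rows
   with Z entirely missing);
2. M-step — beta from all rows, (mu, Sigma) from rows with observed/imputed
   Z only, (gamma, sigma2) from all rows;
3. I-step — refresh the sporadically missing cells of Z with their
   weighted conditional means under the new parameters;
4. the partitioned observed-data log-likelihood, whose absolute change
   drives convergence.

The E/M half of the loop is a genuine (generalized) EM step for fixed
imputations, and the I-step is an exact minorize–maximize update of the
same objective over the missing cells, so the combined loop should never
decrease the log-likelihood; monotonicity is nevertheless monitored, and a
decrease beyond a small slack flags the fit as non-converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datamodel import LucidData, MissingPartition, classify_missing_pattern
from .em_core import (
    LucidParams,
    CovarianceFamily,
    i_step_impute,
    m_step_beta,
    m_step_gaussian_z,
    m_step_outcome,
    observed_loglik,
    responsibilities_complete,
    responsibilities_listwise,
    softmax_probs,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "initial_impute",
    "initialize_params",
    "fit_lucid",
    "count_params",
    "select_k",
    "fit_baseline",
]

#: slack allowed on a log-likelihood decrease before a fit is flagged
MONOTONE_SLACK = 1e-6


@dataclass
class FitConfig:
    """Configuration of a single fit or a K grid search.

    K may be an int or an iterable of ints (grid for :func:`select_k`).
    ``tol`` is on the change in observed-data log-likelihood between outer
    iterations (absolute by default; set ``relative_tol=True`` to scale by
    the magnitude of the current value).
    """

    K: int | tuple = 2
    cov_model: str = "VVV"
    max_iter: int = 1000
    tol: float = 1e-6
    relative_tol: bool = False
    seed: int = 0
    n_init: int = 1
    baseline: str = "lucid"  # or "complete_case" / "mean_impute"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        self.cov_model = str(CovarianceFamily(self.cov_model))
        if self.baseline not in ("lucid", "complete_case", "mean_impute"):
            raise ValueError(f"unknown baseline mode {self.baseline!r}")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if not np.isscalar(d["K"]):
            d["K"] = list(d["K"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        known = {f for f in cls.__dataclass_fields__}
        d = {k: v for k, v in d.items() if k in known}
        if isinstance(d.get("K"), list):
            d["K"] = tuple(d["K"])
        return cls(**d)


@dataclass
class FitResult:
    """Converged parameters, responsibilities and diagnostics of one fit."""

    params: LucidParams
    r: np.ndarray
    Z_imputed: np.ndarray  # observed cells untouched; ic rows left NaN
    loglik_trace: np.ndarray
    bic: float
    n_params: int
    converged: bool
    partition: MissingPartition
    seed: int
    n_iter: int = 0
    monotone_violation: float = 0.0

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def summary(self) -> dict:
        return {
            "K": self.params.K,
            "cov_model": str(self.params.cov_model),
            "loglik": self.loglik,
            "bic": self.bic,
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "partition": {"n_a": self.partition.n_a, "n_b": self.partition.n_b, "n_c": self.partition.n_c},
            "seed": int(self.seed),
        }


def initial_impute(
    Z: np.ndarray,
    mask: np.ndarray,
    partition: MissingPartition,
    seed: int = 0,
    n_sweeps: int = 5,
) -> np.ndarray:
    """Fill sporadically missing cells by iterative column regression.

    Starting from column means, each sweep regresses every incomplete column
    on all other columns (rows where the column is observed, predictors at
    their current fill) and replaces the missing cells with the fitted
    values.  Rows with Z entirely missing are left as NaN — they are handled
    by the likelihood partition, not by imputation.

    With fewer than 2 complete rows the regressions are unidentified and the
    column-mean start is returned unchanged.
    """
    Z = np.array(Z, dtype=float, copy=True)
    mask = np.asarray(mask, dtype=bool)
    ib = partition.ib
    Z[partition.ic] = np.nan
    if ib.size == 0:
        return Z
    iab = partition.iab
    sub = Z[iab].copy()
    sub_mask = mask[iab]

    col_means = np.array([sub[~sub_mask[:, j], j].mean() for j in range(sub.shape[1])])
    for j in range(sub.shape[1]):
        sub[sub_mask[:, j], j] = col_means[j]

    if partition.n_a >= 2 and sub.shape[1] >= 2:
        for _ in range(n_sweeps):
            for j in range(sub.shape[1]):
                rows_miss = sub_mask[:, j]
                if not rows_miss.any():
                    continue
                rows_obs = ~rows_miss
                others = np.delete(np.arange(sub.shape[1]), j)
                X_obs = np.column_stack([np.ones(rows_obs.sum()), sub[rows_obs][:, others]])
                coef, *_ = np.linalg.lstsq(X_obs, sub[rows_obs, j], rcond=None)
                X_mis = np.column_stack([np.ones(rows_miss.sum()), sub[rows_miss][:, others]])
                sub[rows_miss, j] = X_mis @ coef

    Z[iab] = sub
    Z[partition.ic] = np.nan
    return Z


def initialize_params(
    data: LucidData,
    Z_filled: np.ndarray,
    partition: MissingPartition,
    K: int,
    cov_model: str = "VVV",
    seed: int = 0,
) -> LucidParams:
    """Moment-based starting values from a seeded k-means labelling.

    k-means on the (imputed) Z rows of ia and ib yields hard labels; mu and
    Sigma come from per-cluster moments, beta from a multinomial-logistic
    fit of the labels on G, and (gamma, sigma2) from per-cluster moments of
    Y.  Rows with Z entirely missing are assigned, for initialization only,
    to their most probable cluster under the fitted softmax.
    """
    iab = partition.iab
    Zc = Z_filled[iab]
    n_ab = iab.size
    if K == 1:
        labels = np.zeros(n_ab, dtype=int)
    else:
        labels = None
        for attempt in range(10):
            km = KMeans(n_clusters=K, n_init=3, random_state=int(seed) + attempt)
            cand = km.fit_predict(Zc)
            if np.bincount(cand, minlength=K).min() > 0:
                labels = cand
                break
        if labels is None:
            raise ValueError(f"k-means produced an empty cluster in 10 attempts (K={K}, n={n_ab})")

    r_hard = np.zeros((n_ab, K))
    r_hard[np.arange(n_ab), labels] = 1.0
    mu, Sigma = m_step_gaussian_z(Zc, r_hard, cov_model)
    beta = m_step_beta(data.G[iab], r_hard) if K > 1 else np.zeros((1, data.p + 1))

    # extend hard labels to ic rows through the exposure model
    all_labels = np.empty(data.n, dtype=int)
    all_labels[iab] = labels
    if partition.ic.size:
        probs = softmax_probs(data.G[partition.ic], beta)
        all_labels[partition.ic] = probs.argmax(axis=1)
    r_all = np.zeros((data.n, K))
    r_all[np.arange(data.n), all_labels] = 1.0
    # guard: a cluster can lose all mass on Y if ic assignment is lopsided
    if (r_all.sum(axis=0) == 0).any():
        r_all = np.full((data.n, K), 1.0 / K)
    gamma, sigma2 = m_step_outcome(data.Y, r_all)
    return LucidParams(beta=beta, mu=mu, Sigma=Sigma, gamma=gamma, sigma2=sigma2, cov_model=cov_model)


def count_params(K: int, p: int, m: int, cov_model: str = "VVV") -> int:
    """Free-parameter count used by the BIC.

    (K-1)(p+1) softmax coefficients, K m cluster means, the family-specific
    covariance count (VVV: K m(m+1)/2; EEE: m(m+1)/2; VII: K; EII: 1),
    plus K outcome means and K outcome variances.
    """
    cov_model = CovarianceFamily(cov_model)
    n_sigma = {
        "VVV": K * m * (m + 1) // 2,
        "EEE": m * (m + 1) // 2,
        "VII": K,
        "EII": 1,
    }[str(cov_model)]
    return (K - 1) * (p + 1) + K * m + n_sigma + K + K


def _em_loop(
    data: LucidData,
    partition: MissingPartition,
    params: LucidParams,
    Z_work: np.ndarray,
    config: FitConfig,
) -> tuple[LucidParams, np.ndarray, np.ndarray, np.ndarray, bool, float]:
    """Run Algorithm-style E/M/I iterations until the log-likelihood settles."""
    iab = partition.iab
    ic = partition.ic
    ib = partition.ib
    K = params.K
    n = data.n

    ll = observed_loglik(data.G, Z_work, data.Y, partition, params)
    trace = [ll]
    converged = False
    worst_drop = 0.0
    r = np.full((n, K), 1.0 / K)

    for _ in range(config.max_iter):
        # E-step
        r = np.empty((n, K))
        r[iab] = responsibilities_complete(data.G[iab], Z_work[iab], data.Y[iab], params)
        if ic.size:
            r[ic] = responsibilities_listwise(data.G[ic], data.Y[ic], params)
        # M-step
        beta = m_step_beta(data.G, r, beta_init=params.beta) if K > 1 else params.beta
        mu, Sigma = m_step_gaussian_z(Z_work[iab], r[iab], config.cov_model)
        gamma, sigma2 = m_step_outcome(data.Y, r)
        params = LucidParams(
            beta=beta, mu=mu, Sigma=Sigma, gamma=gamma, sigma2=sigma2, cov_model=config.cov_model
        )
        # I-step: weight each cluster by the row's Z-free responsibility at the
        # NEW parameters; together with the Gaussian density factor inside
        # i_step_impute this is the full posterior at (theta_new, Z_current),
        # making the imputation an exact minorize-maximize update.
        if ib.size:
            r_zfree = responsibilities_listwise(data.G[ib], data.Y[ib], params)
            for t_row, i in enumerate(ib):
                Z_work[i] = i_step_impute(Z_work[i], data.mask[i], r_zfree[t_row], params)
        ll_new = observed_loglik(data.G, Z_work, data.Y, partition, params)
        delta = ll_new - ll
        if delta < -MONOTONE_SLACK:
            worst_drop = max(worst_drop, -delta)
        trace.append(ll_new)
        denom = max(1.0, abs(ll_new)) if config.relative_tol else 1.0
        if abs(delta) / denom < config.tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new

    if worst_drop > 0:
        converged = False
    return params, r, Z_work, np.asarray(trace), converged, worst_drop


def fit_lucid(data: LucidData, config: FitConfig) -> FitResult:
    """Fit the LUCID model with integrated handling of missing omics data.

    Runs ``n_init`` restarts (seeded k-means initializations), keeps the one
    with the highest final log-likelihood, and relabels clusters in
    increasing order of the outcome mean gamma so that output ordering is
    deterministic despite label-invariance of the likelihood.
    """
    K = config.K
    if not np.isscalar(K):
        raise ValueError("fit_lucid takes a single K; use select_k for a grid")
    K = int(K)
    partition = classify_missing_pattern(data.mask)

    best: FitResult | None = None
    errors: list[str] = []
    for restart in range(config.n_init):
        seed = int(config.seed) + restart
        try:
            Z0 = initial_impute(data.Z, data.mask, partition, seed=seed)
            params0 = initialize_params(data, Z0, partition, K, config.cov_model, seed=seed)
            params, r, Z_work, trace, converged, drop = _em_loop(
                data, partition, params0, Z0, config
            )
        except ValueError as err:
            errors.append(str(err))
            continue
        result = FitResult(
            params=params,
            r=r,
            Z_imputed=Z_work,
            loglik_trace=trace,
            bic=float("nan"),
            n_params=count_params(K, data.p, data.m, config.cov_model),
            converged=converged,
            partition=partition,
            seed=seed,
            n_iter=len(trace) - 1,
            monotone_violation=drop,
        )
        if best is None or result.loglik > best.loglik:
            best = result
    if best is None:
        raise ValueError("all restarts failed: " + "; ".join(errors))

    order = np.argsort(best.params.gamma, kind="stable")
    if not np.array_equal(order, np.arange(K)):
        best.params = best.params.relabel(order)
        best.r = best.r[:, order]
    best.bic = -2.0 * best.loglik + best.n_params * np.log(data.n)
    # observed cells must survive the fit bit-identically
    best.Z_imputed[~data.mask] = data.Z[~data.mask]
    best.Z_imputed[partition.ic] = np.nan
    return best


def select_k(data: LucidData, config: FitConfig) -> tuple[pd.DataFrame, int, dict]:
    """Grid search over K by BIC (lower is better).

    Returns the per-K table, the chosen K and a dict of FitResults.  A K
    whose fit fails is recorded with NaN BIC and skipped; if every K fails,
    an error is raised.
    """
    grid = [int(config.K)] if np.isscalar(config.K) else [int(k) for k in config.K]
    rows = []
    fits: dict[int, FitResult] = {}
    for K in grid:
        cfg_k = FitConfig(**{**config.to_dict(), "K": K})
        try:
            res = fit_lucid(data, cfg_k)
        except ValueError as err:
            rows.append({"K": K, "loglik": np.nan, "n_params": np.nan, "bic": np.nan, "converged": False,
                         "error": str(err)})
            continue
        fits[K] = res
        rows.append({"K": K, "loglik": res.loglik, "n_params": res.n_params, "bic": res.bic,
                     "converged": res.converged, "error": ""})
    table = pd.DataFrame(rows)
    if table["bic"].isna().all():
        raise ValueError("every K in the grid failed to fit")
    chosen = int(table.loc[table["bic"].idxmin(), "K"])
    return table, chosen, fits


def fit_baseline(data: LucidData, config: FitConfig) -> FitResult:
    """Fit a naive-handling baseline: complete-case or mean imputation.

    complete_case drops every row with any missing omics cell and fits the
    complete-data model; mean_impute replaces every missing cell (including
    entire missing rows) with its column mean over observed cells, then fits
    as if complete.  With no missingness both coincide with :func:`fit_lucid`.
    """
    mode = config.baseline
    if mode == "lucid":
        return fit_lucid(data, config)
    partition = classify_missing_pattern(data.mask)
    K = int(config.K) if np.isscalar(config.K) else max(int(k) for k in config.K)
    if mode == "complete_case":
        ia = partition.ia
        if ia.size < 10 * K:
            raise ValueError(
                f"complete-case analysis needs at least {10 * K} complete rows, found {ia.size}"
            )
        sub = LucidData(
            G=data.G[ia], Z=data.Z[ia], Y=data.Y[ia],
            mask=np.zeros((ia.size, data.m), dtype=bool),
            row_ids=data.row_ids[ia],
        )
        return fit_lucid(sub, FitConfig(**{**config.to_dict(), "baseline": "lucid"}))
    if mode == "mean_impute":
        Z = data.Z.copy()
        for j in range(data.m):
            obs = ~data.mask[:, j]
            Z[~obs, j] = Z[obs, j].mean()
        filled = LucidData(
            G=data.G, Z=Z, Y=data.Y,
            mask=np.zeros_like(data.mask), row_ids=data.row_ids,
        )
        return fit_lucid(filled, FitConfig(**{**config.to_dict(), "baseline": "lucid"}))
    raise ValueError(f"unknown baseline mode {mode!r}")
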