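"""Out-of-sample prediction, clustering AUC, estimator bias summaries and
the replication-study driver comparing missing-data strategies.

The headline comparison mirrors a standard missing-data benchmark: simulate
a large cohort from known parameters, hold out a validation set, then per
replicate subsample a training set, inject list-wise missingness at a grid
of ratios, fit the integrated model and the naive baselines, and score each
fit by (a) its parameter estimates against the truth and (b) the AUC of the
posterior inclusion probability for the high-outcome cluster against the
known validation labels — computed without using the validation outcome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from .em_core import LucidParams, log_mvn_density, log_softmax_probs
from .fitting import FitConfig, fit_baseline
from .simulate import SimDesign, simulate_lucid_data, subsample, train_validation_split, inject_missing

__all__ = [
    "MethodComparison",
    "predict_posterior",
    "predict_outcome",
    "auc_pip",
    "align_and_bias",
    "run_replication_study",
]


def predict_posterior(
    G_new: np.ndarray,
    Z_new: np.ndarray,
    params: LucidParams,
    mask: np.ndarray | None = None,
    Y_new: np.ndarray | None = None,
    use_outcome: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior cluster probabilities and hard labels for new observations.

    By default the outcome is not used: r is proportional to
    S(X=j|G) * phi(Z_obs | mu_j, Sigma_j), where for rows with partially
    missing Z the Gaussian marginal on the observed coordinates is used and
    for rows with fully missing Z only the softmax term remains.  Hard
    labels take the argmax, with ties broken toward the lower index.
    """
    G_new = np.atleast_2d(np.asarray(G_new, dtype=float))
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    n = G_new.shape[0]
    if Z_new.shape[0] != n:
        raise ValueError("G_new and Z_new row counts differ")
    if G_new.shape[1] != params.p or Z_new.shape[1] != params.m:
        raise ValueError("column counts do not match the fitted parameters")
    if mask is None:
        mask = np.isnan(Z_new)
    mask = np.asarray(mask, dtype=bool)

    logr = log_softmax_probs(G_new, params.beta)
    if use_outcome:
        if Y_new is None:
            raise ValueError("use_outcome=True requires Y_new")
        Y_new = np.asarray(Y_new, dtype=float).ravel()
        for j in range(params.K):
            logr[:, j] += -0.5 * (
                np.log(2 * np.pi * params.sigma2[j]) + (Y_new - params.gamma[j]) ** 2 / params.sigma2[j]
            )

    # group rows by missing pattern so each pattern costs one marginal density
    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(mask[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        pat = np.frombuffer(key, dtype=bool)
        if pat.all():
            continue  # softmax (and outcome) terms only
        obs = ~pat
        rows = np.asarray(rows)
        Zo = Z_new[np.ix_(rows, np.flatnonzero(obs))]
        for j in range(params.K):
            Sj = params.Sigma[j][np.ix_(obs, obs)]
            logr[rows, j] += log_mvn_density(Zo, params.mu[j][obs], Sj, j)

    r = np.exp(logr - logsumexp(logr, axis=1, keepdims=True))
    r /= r.sum(axis=1, keepdims=True)
    return r, r.argmax(axis=1)


def predict_outcome(r_new: np.ndarray, params: LucidParams) -> np.ndarray:
    """Posterior-mixture outcome prediction: Y_hat_i = sum_j r_ij gamma_j."""
    r_new = np.atleast_2d(np.asarray(r_new, dtype=float))
    return r_new @ params.gamma


def auc_pip(pip: np.ndarray, labels: np.ndarray) -> float:
    """Rank (Mann–Whitney) AUC of posterior inclusion probabilities against
    binary cluster labels, with tie correction."""
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; AUC undefined")
    return float(roc_auc_score(labels, np.asarray(pip, dtype=float).ravel()))


def _beta_delta(est: LucidParams, truth: LucidParams) -> np.ndarray:
    return est.beta[1:] - truth.beta[1:]


def align_and_bias(est: LucidParams, truth: LucidParams) -> dict:
    """Relabel the estimate to match the truth and report estimate - truth.

    Clusters are matched in increasing order of the outcome mean gamma; when
    the truth's gammas tie, the permutation minimizing total distance
    between cluster means of Z is used instead.  Returns deltas for the
    softmax coefficients (non-reference rows), omics means, outcome means,
    and outcome variances.
    """
    if est.K != truth.K:
        raise ValueError(f"cluster count mismatch: estimate has {est.K}, truth has {truth.K}")
    K = est.K
    gt = truth.gamma
    if np.unique(np.round(gt, 12)).size == K:
        truth_order = np.argsort(gt, kind="stable")
        est_order = np.argsort(est.gamma, kind="stable")
        # est cluster est_order[i] plays the role of truth cluster truth_order[i]
        perm = np.empty(K, dtype=int)
        perm[:] = est_order[np.argsort(truth_order, kind="stable")]
    else:
        best_perm, best_cost = None, np.inf
        for cand in itertools.permutations(range(K)):
            cost = sum(np.linalg.norm(est.mu[cand[j]] - truth.mu[j]) for j in range(K))
            if cost < best_cost:
                best_perm, best_cost = np.asarray(cand), cost
        perm = best_perm
    # relabel also re-references beta so row 0 of the aligned estimate is zero
    aligned = est.relabel(perm)
    return {
        "permutation": perm,
        "beta": _beta_delta(aligned, truth),
        "mu": aligned.mu - truth.mu,
        "gamma": aligned.gamma - truth.gamma,
        "sigma2": aligned.sigma2 - truth.sigma2,
        "aligned": aligned,
    }


@dataclass
class MethodComparison:
    """Long-format per-fit records and their aggregates."""

    records: pd.DataFrame   # method, ratio, replicate, parameter, estimate, truth
    auc: pd.DataFrame       # method, ratio, replicate, auc
    failures: pd.DataFrame  # method, ratio, replicate, error

    def aggregate_estimates(self) -> pd.DataFrame:
        g = self.records.groupby(["method", "ratio", "parameter"], sort=True)
        out = g.agg(
            mean_estimate=("estimate", "mean"),
            sd_estimate=("estimate", "std"),
            truth=("truth", "first"),
            n_reps=("estimate", "size"),
        ).reset_index()
        out["bias"] = out["mean_estimate"] - out["truth"]
        return out

    def aggregate_auc(self) -> pd.DataFrame:
        g = self.auc.groupby(["method", "ratio"], sort=True)
        return g.agg(
            median_auc=("auc", "median"),
            sd_auc=("auc", "std"),
            n_reps=("auc", "size"),
        ).reset_index()


def _flatten_estimates(aligned: LucidParams, truth: LucidParams) -> list[tuple[str, float, float]]:
    rows = []
    for j in range(1, truth.K):
        for c in range(truth.p + 1):
            name = f"beta[{j},{'intercept' if c == 0 else f'G{c-1}'}]"
            rows.append((name, float(aligned.beta[j, c]), float(truth.beta[j, c])))
    for j in range(truth.K):
        for c in range(truth.m):
            rows.append((f"mu[{j},Z{c}]", float(aligned.mu[j, c]), float(truth.mu[j, c])))
    for j in range(truth.K):
        rows.append((f"gamma[{j}]", float(aligned.gamma[j]), float(truth.gamma[j])))
    return rows


def run_replication_study(
    design: SimDesign | None = None,
    ratio_grid: tuple = (0.1, 0.3, 0.5),
    methods: tuple = ("lucid", "complete_case", "mean_impute"),
    n_reps: int = 50,
    seed: int = 0,
    n_sub: int = 2000,
    fit_kwargs: dict | None = None,
    truth_params: LucidParams | None = None,
) -> MethodComparison:
    """Replicated comparison of missing-data strategies over a ratio grid.

    One master cohort is simulated and split once; each replicate subsamples
    ``n_sub`` training rows, injects list-wise MCAR missingness at each
    ratio, fits each method, aligns its estimates to the truth, and scores
    the validation AUC of the high-outcome cluster's posterior inclusion
    probability (outcome unused at prediction time).  Individual fit
    failures are recorded and excluded from the aggregates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    design = design or SimDesign()
    fit_kwargs = fit_kwargs or {}
    rng = np.random.default_rng(seed)
    data, truth = simulate_lucid_data(design, true_params=truth_params, seed=int(rng.integers(2**31)))
    n_valid = min(2000, design.n // 5)
    n_train = design.n - n_valid
    train, train_labels, valid, valid_labels = train_validation_split(
        data, truth, n_train=n_train, n_valid=n_valid, seed=int(rng.integers(2**31))
    )

    est_rows, auc_rows, fail_rows = [], [], []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        sub, _ = subsample(train, train_labels, min(n_sub, train.n), seed=rep_seed)
        for ratio in ratio_grid:
            masked = (
                sub
                if ratio == 0
                else inject_missing(sub, mechanism=design.mechanism, ratio=ratio, seed=rep_seed + 1)
            )
            for method in methods:
                cfg = FitConfig(K=design.K, seed=rep_seed, baseline=method, **fit_kwargs)
                try:
                    res = fit_baseline(masked, cfg)
                    bias = align_and_bias(res.params, truth.params)
                    r_valid, _ = predict_posterior(valid.G, valid.Z, bias["aligned"])
                    high = truth.params.K - 1
                    auc = auc_pip(r_valid[:, high], (valid_labels == high).astype(int))
                except ValueError as err:
                    fail_rows.append({"method": method, "ratio": ratio, "replicate": rep, "error": str(err)})
                    continue
                auc_rows.append({"method": method, "ratio": ratio, "replicate": rep, "auc": auc})
                for name, estv, truv in _flatten_estimates(bias["aligned"], truth.params):
                    est_rows.append(
                        {"method": method, "ratio": ratio, "replicate": rep,
                         "parameter": name, "estimate": estv, "truth": truv}
                    )
    return MethodComparison(
        records=pd.DataFrame(est_rows),
        auc=pd.DataFrame(auc_rows),
        failures=pd.DataFrame(fail_rows, columns=["method", "ratio", "replicate", "error"]),
    )
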