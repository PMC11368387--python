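"""Synthetic data generation for the exposure → latent cluster → omics/outcome model.

The generator draws G as iid standard normal exposures, assigns each row to
a latent cluster through the softmax of G, then draws the omics vector from
the cluster's multivariate Gaussian and the outcome from the cluster's
univariate Gaussian.  The default study design is n=10000 rows, p=10
exposures, m=4 omics features and K=2 clusters, split 8000/2000 into
training and validation; replication studies subsample 2000 training rows
per replicate.

Missingness injectors cover three mechanisms:

* ``listwise_mcar`` — an exact quota of rows, chosen uniformly, loses its
  entire omics vector;
* ``listwise_mar_y`` — the quota is drawn without replacement with
  probability increasing in the outcome (rows with high Y are more likely
  to go missing), a missing-at-random mechanism since Y is observed;
* ``sporadic_mcar`` — each cell is masked independently; rows that happen
  to lose every cell become list-wise missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .datamodel import LucidData
from .em_core import LucidParams, softmax_probs

__all__ = [
    "SimDesign",
    "SimTruth",
    "default_truth",
    "simulate_lucid_data",
    "train_validation_split",
    "inject_missing",
]

MECHANISMS = ("listwise_mcar", "listwise_mar_y", "sporadic_mcar")


@dataclass
class SimDesign:
    """Dimensions and missingness settings of a simulated study."""

    n: int = 10_000
    p: int = 10
    m: int = 4
    K: int = 2
    mechanism: str = "listwise_mcar"
    missing_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; choose from {MECHANISMS}")
        if not 0.0 <= self.missing_ratio < 1.0:
            raise ValueError("missing_ratio must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth bundled with a simulated dataset."""

    params: LucidParams
    labels: np.ndarray  # 0-based cluster assignments
    seed: int
    design: SimDesign = field(default_factory=SimDesign)


def default_truth(design: SimDesign | None = None) -> LucidParams:
    """Reference parameter values producing detectable but realistic effects.

    Cluster 2's log-odds load 0.3 on the first five exposures (zero
    intercept, zero elsewhere); the clusters sit at -0.5 / +0.5 on every
    omics feature with identity covariance; the outcome means are -1 and +1
    with unit variance.  The construction is symmetric, so each cluster
    captures about half the sample.
    """
    design = design or SimDesign()
    if design.K != 2:
        raise ValueError("default truth is defined for the two-cluster design")
    beta = np.zeros((2, design.p + 1))
    n_active = min(5, design.p)
    beta[1, 1 : 1 + n_active] = 0.3
    mu = np.vstack([np.full(design.m, -0.5), np.full(design.m, 0.5)])
    Sigma = np.repeat(np.eye(design.m)[None], 2, axis=0)
    return LucidParams(
        beta=beta, mu=mu, Sigma=Sigma, gamma=np.array([-1.0, 1.0]), sigma2=np.array([1.0, 1.0])
    )


def simulate_lucid_data(
    design: SimDesign,
    true_params: LucidParams | None = None,
    seed: int = 0,
) -> tuple[LucidData, SimTruth]:
    """Draw a complete dataset from the generative model.

    G ~ iid N(0,1); X_i ~ Multinomial(softmax(G_i; beta));
    Z_i ~ MVN(mu_{X_i}, Sigma_{X_i}); Y_i ~ N(gamma_{X_i}, sigma2_{X_i}).
    """
    params = true_params if true_params is not None else default_truth(design)
    if params.K != design.K or params.p != design.p or params.m != design.m:
        raise ValueError("true_params dimensions do not match the design")
    for j in range(params.K):
        if np.linalg.eigvalsh(params.Sigma[j]).min() <= 0:
            raise ValueError(f"Sigma for cluster {j} is not positive definite")

    rng = np.random.default_rng(seed)
    G = rng.standard_normal((design.n, design.p))
    probs = softmax_probs(G, params.beta)
    u = rng.random(design.n)
    labels = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    Z = np.empty((design.n, design.m))
    chol = [np.linalg.cholesky(params.Sigma[j]) for j in range(params.K)]
    eps = rng.standard_normal((design.n, design.m))
    for j in range(params.K):
        rows = labels == j
        Z[rows] = params.mu[j] + eps[rows] @ chol[j].T
    Y = params.gamma[labels] + np.sqrt(params.sigma2[labels]) * rng.standard_normal(design.n)

    data = LucidData(G=G, Z=Z, Y=Y, mask=np.zeros((design.n, design.m), dtype=bool))
    return data, SimTruth(params=params, labels=labels, seed=int(seed), design=design)


def _subset(data: LucidData, truth: SimTruth, idx: np.ndarray) -> tuple[LucidData, np.ndarray]:
    sub = LucidData(
        G=data.G[idx], Z=data.Z[idx], Y=data.Y[idx],
        mask=data.mask[idx], row_ids=data.row_ids[idx],
    )
    return sub, truth.labels[idx]


def train_validation_split(
    data: LucidData,
    truth: SimTruth,
    n_train: int = 8000,
    n_valid: int = 2000,
    seed: int = 0,
):
    """Disjoint seeded split into training and validation sets (with labels)."""
    if n_train + n_valid > data.n:
        raise ValueError(f"requested {n_train}+{n_valid} rows but only {data.n} available")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    tr, va = perm[:n_train], perm[n_train : n_train + n_valid]
    train, train_labels = _subset(data, truth, tr)
    valid, valid_labels = _subset(data, truth, va)
    return train, train_labels, valid, valid_labels


def subsample(data: LucidData, labels: np.ndarray, n_sub: int, seed: int = 0):
    """Draw a seeded replicate of n_sub rows without replacement."""
    if n_sub > data.n:
        raise ValueError("subsample larger than the dataset")
    rng = np.random.default_rng(seed)
    idx = rng.choice(data.n, size=n_sub, replace=False)
    sub = LucidData(
        G=data.G[idx], Z=data.Z[idx], Y=data.Y[idx],
        mask=data.mask[idx], row_ids=data.row_ids[idx],
    )
    return sub, labels[idx]


def _mar_y_weights(Y: np.ndarray) -> np.ndarray:
    """Selection weights increasing in Y, scaled so the top Y-quartile's
    missingness odds are about three times the bottom quartile's."""
    q1, q3 = np.quantile(Y, [0.25, 0.75])
    top_mean = Y[Y >= q3].mean()
    bot_mean = Y[Y <= q1].mean()
    b = np.log(3.0) / max(top_mean - bot_mean, 1e-12)
    a = -b * np.median(Y)
    return expit(a + b * Y)


def inject_missing(
    data: LucidData,
    mechanism: str = "listwise_mcar",
    ratio: float = 0.3,
    seed: int = 0,
) -> LucidData:
    """Return a copy of the data with a missingness mask injected into Z.

    List-wise mechanisms blank an exact quota of round(ratio * n) rows so
    that per-replicate missing counts are deterministic; the sporadic
    mechanism masks cells iid Bernoulli(ratio).
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; choose from {MECHANISMS}")
    if not 0.0 <= ratio <= 0.9:
        raise ValueError("ratio must be in [0, 0.9]")
    rng = np.random.default_rng(seed)
    mask = data.mask.copy()
    if ratio > 0:
        if mechanism in ("listwise_mcar", "listwise_mar_y"):
            n_miss = int(round(ratio * data.n))
            if mechanism == "listwise_mcar":
                rows = rng.choice(data.n, size=n_miss, replace=False)
            else:
                w = _mar_y_weights(data.Y)
                rows = rng.choice(data.n, size=n_miss, replace=False, p=w / w.sum())
            mask[rows, :] = True
        else:  # sporadic_mcar
            mask |= rng.random(mask.shape) < ratio
    complete_rows = int((~mask.any(axis=1)).sum())
    if complete_rows < 2:
        raise ValueError("missingness injection would leave fewer than 2 complete rows")
    Z = data.Z.copy()
    return LucidData(G=data.G.copy(), Z=Z, Y=data.Y.copy(), mask=mask, row_ids=data.row_ids.copy())
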