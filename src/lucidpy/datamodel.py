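"""Observed-data containers and the three-way missingness partition.

Missingness in the omics matrix Z is carried as an explicit boolean mask
(True = missing) alongside the numeric matrix, never as sentinel values:
during a fit the missing cells of Z hold whatever imputation is current,
and only the mask distinguishes imputed from observed entries.

Rows fall into three disjoint groups by their missing pattern:

* ``ia`` — Z fully observed,
* ``ib`` — some but not all cells of Z missing (sporadic missingness),
* ``ic`` — Z entirely missing (list-wise missingness).

The partitioned likelihood treats ``ib`` rows as complete once imputed,
while ``ic`` rows contribute only their exposure and outcome terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LucidData",
    "MissingPartition",
    "ValidationReport",
    "classify_missing_pattern",
    "validate_data",
]


@dataclass
class MissingPartition:
    """Disjoint row-index sets by missing pattern of Z (0-based)."""

    ia: np.ndarray  # rows with Z fully observed
    ib: np.ndarray  # rows with >=1 but < m cells missing
    ic: np.ndarray  # rows with all m cells missing

    @property
    def n_a(self) -> int:
        return self.ia.size

    @property
    def n_b(self) -> int:
        return self.ib.size

    @property
    def n_c(self) -> int:
        return self.ic.size

    @property
    def n(self) -> int:
        return self.n_a + self.n_b + self.n_c

    @property
    def iab(self) -> np.ndarray:
        """Rows whose Z enters the Gaussian likelihood (sorted union of ia, ib)."""
        return np.sort(np.concatenate([self.ia, self.ib]))


@dataclass
class LucidData:
    """The observed triple (G, Z, Y) with a missingness mask for Z.

    Parameters
    ----------
    G : (n, p) float array
        Exposures; must be complete and finite.
    Z : (n, m) float array
        Omics measurements.  Cells flagged in ``mask`` may hold NaN or any
        placeholder; observed cells must be finite.
    Y : (n,) float array
        Continuous outcome; must be complete and finite.
    mask : (n, m) bool array, optional
        True where Z is missing.  Defaults to ``isnan(Z)``.
    row_ids : sequence, optional
        Stable labels for user-facing output; defaults to 0..n-1.
    """

    G: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    mask: np.ndarray | None = None
    row_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if self.G.ndim != 2 or self.Z.ndim != 2:
            raise ValueError("G and Z must be 2-D matrices")
        n = self.G.shape[0]
        if self.Z.shape[0] != n or self.Y.shape[0] != n:
            raise ValueError(
                f"row counts differ: G has {n}, Z has {self.Z.shape[0]}, Y has {self.Y.shape[0]}"
            )
        if n < 2:
            raise ValueError("need at least 2 observations")
        if self.G.shape[1] < 1 or self.Z.shape[1] < 1:
            raise ValueError("G and Z need at least one column each")
        if self.mask is None:
            self.mask = np.isnan(self.Z)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.Z.shape:
                raise ValueError("mask shape must match Z")
            # NaNs outside the mask would silently poison the likelihood
            if np.isnan(self.Z[~self.mask]).any():
                raise ValueError("Z contains NaN cells not covered by the mask")
        if self.row_ids is None:
            self.row_ids = np.arange(n)
        else:
            self.row_ids = np.asarray(self.row_ids)
            if self.row_ids.shape[0] != n:
                raise ValueError("row_ids length must equal n")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def p(self) -> int:
        return self.G.shape[1]

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    def partition(self) -> MissingPartition:
        return classify_missing_pattern(self.mask)


def classify_missing_pattern(mask: np.ndarray) -> MissingPartition:
    """Split row indices into (fully observed, partial, fully missing) sets.

    Raises
    ------
    ValueError
        If the mask is empty, or some omics feature has no observed value
        among the rows that contribute to the Gaussian likelihood (its mean
        and variance would be unidentifiable).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2-D boolean array")
    n_missing = mask.sum(axis=1)
    m = mask.shape[1]
    ia = np.flatnonzero(n_missing == 0)
    ic = np.flatnonzero(n_missing == m)
    ib = np.flatnonzero((n_missing > 0) & (n_missing < m))
    iab = np.concatenate([ia, ib])
    if iab.size == 0:
        raise ValueError("every row of Z is fully missing; the omics model is unidentifiable")
    col_observed = (~mask[iab]).sum(axis=0)
    dead = np.flatnonzero(col_observed == 0)
    if dead.size:
        raise ValueError(
            f"omics column(s) {dead.tolist()} have no observed values; "
            "their Gaussian parameters are unidentifiable"
        )
    return MissingPartition(ia=ia, ib=ib, ic=ic)


@dataclass
class ValidationReport:
    n: int
    p: int
    m: int
    missing_fraction: np.ndarray  # per-column fraction of missing Z cells
    constant_g_columns: list = field(default_factory=list)
    constant_z_columns: list = field(default_factory=list)
    partition_counts: tuple = (0, 0, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z_column": np.arange(self.m), "missing_fraction": self.missing_fraction}
        )


def validate_data(data: LucidData) -> ValidationReport:
    """Check model preconditions and summarize the missingness structure.

    The model assumes a complete exposure matrix and a complete continuous
    outcome; any missing or non-finite value there is an error, not a
    warning, because neither enters the imputation machinery.
    """
    if np.isnan(data.Y).any():
        raise ValueError("outcome must be complete (Y contains missing values)")
    if not np.isfinite(data.Y).all():
        raise ValueError("outcome contains non-finite values")
    if np.isnan(data.G).any():
        raise ValueError("exposures must be complete (G contains missing values)")
    if not np.isfinite(data.G).all():
        raise ValueError("exposures contain non-finite values")
    observed = data.Z[~data.mask]
    if observed.size and not np.isfinite(observed).all():
        raise ValueError("observed cells of Z contain non-finite values")

    part = classify_missing_pattern(data.mask)  # also rejects all-missing columns
    frac = data.mask.mean(axis=0)

    const_g = [j for j in range(data.p) if np.ptp(data.G[:, j]) == 0.0]
    const_z = []
    for j in range(data.m):
        col = data.Z[~data.mask[:, j], j]
        if col.size and np.ptp(col) == 0.0:
            const_z.append(j)

    return ValidationReport(
        n=data.n,
        p=data.p,
        m=data.m,
        missing_fraction=frac,
        constant_g_columns=const_g,
        constant_z_columns=const_z,
        partition_counts=(part.n_a, part.n_b, part.n_c),
    )
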