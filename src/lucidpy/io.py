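"""Delimited-text readers and writers for the observed triple (G, Z, Y).

Input is either three files (exposures, omics, outcome) or one wide file
whose columns are selected by prefix (e.g. ``G_*``, ``Z_*`` and an outcome
column).  Missing omics cells are empty strings or the literal ``NA``;
readers translate them into the boolean mask, never into sentinel numbers.
Categorical exposure columns (e.g. quartile labels) are dummy-coded with
the first level as reference.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import LucidData
from .fitting import FitResult

__all__ = [
    "read_table",
    "read_lucid_data",
    "read_lucid_wide",
    "write_lucid_data",
    "write_fit_result",
]

NA_VALUES = ["", "NA", "NaN", "nan"]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV or TSV (sniffed from the extension) with a header row."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        return pd.read_csv(path, sep=sep, na_values=NA_VALUES, keep_default_na=False)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed table {path}: {err}") from err


def _dummy_code(df: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code non-numeric columns, first level as reference."""
    out = []
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            out.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True, dtype=float)
            out.append(dummies)
    return pd.concat(out, axis=1)


def read_lucid_data(g_path, z_path, y_path) -> LucidData:
    """Assemble a dataset from three positionally aligned files."""
    g_df = read_table(g_path)
    z_df = read_table(z_path)
    y_df = read_table(y_path)
    if not (len(g_df) == len(z_df) == len(y_df)):
        raise ValueError(
            f"row counts differ: G={len(g_df)}, Z={len(z_df)}, Y={len(y_df)}"
        )
    G = _dummy_code(g_df)
    if G.isna().any().any():
        raise ValueError("exposure file contains missing values; G must be complete")
    Z = z_df.astype(float)
    y_col = y_df.columns[0]
    Y = y_df[y_col].astype(float)
    if Y.isna().any():
        raise ValueError("outcome must be complete")
    mask = Z.isna().to_numpy()
    return LucidData(G=G.to_numpy(), Z=Z.to_numpy(), Y=Y.to_numpy(), mask=mask,
                     row_ids=np.arange(len(g_df)))


def read_lucid_wide(path, g_prefix="G", z_prefix="Z", y_column="Y") -> LucidData:
    """Assemble a dataset from one wide file using column-name prefixes."""
    df = read_table(path)
    g_cols = [c for c in df.columns if c.startswith(g_prefix)]
    z_cols = [c for c in df.columns if c.startswith(z_prefix)]
    if not g_cols or not z_cols or y_column not in df.columns:
        raise ValueError(
            f"wide file must contain {g_prefix}*-prefixed, {z_prefix}*-prefixed and {y_column!r} columns"
        )
    G = _dummy_code(df[g_cols])
    if G.isna().any().any():
        raise ValueError("exposure columns contain missing values; G must be complete")
    Z = df[z_cols].astype(float)
    Y = df[y_column].astype(float)
    if Y.isna().any():
        raise ValueError("outcome must be complete")
    return LucidData(G=G.to_numpy(), Z=Z.to_numpy(), Y=Y.to_numpy(),
                     mask=Z.isna().to_numpy(), row_ids=np.arange(len(df)))


def write_lucid_data(data: LucidData, outdir: str | Path, stem: str = "sim") -> dict:
    """Write G/Z/Y as CSVs (missing Z cells as NA); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g_path = outdir / f"{stem}_G.csv"
    z_path = outdir / f"{stem}_Z.csv"
    y_path = outdir / f"{stem}_Y.csv"
    pd.DataFrame(data.G, columns=[f"G{j}" for j in range(data.p)]).to_csv(g_path, index=False)
    Z = data.Z.astype(object).copy()
    Z[data.mask] = np.nan
    pd.DataFrame(Z, columns=[f"Z{j}" for j in range(data.m)]).to_csv(z_path, index=False, na_rep="NA")
    pd.DataFrame({"Y": data.Y}).to_csv(y_path, index=False)
    return {"G": str(g_path), "Z": str(z_path), "Y": str(y_path)}


SUMMARY_SCHEMA_VERSION = 1


def write_fit_result(result: FitResult, data: LucidData, outdir: str | Path) -> dict:
    """Emit the standard artifact set for one fit.

    params.csv (long format), responsibilities.csv, imputed_Z.csv with the
    mask retained as companion columns, loglik_trace.csv and summary.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = result.params

    rows = []
    for j in range(p.K):
        for c in range(p.p + 1):
            rows.append({"parameter": "beta", "cluster": j,
                         "component": "intercept" if c == 0 else f"G{c-1}", "value": p.beta[j, c]})
        for c in range(p.m):
            rows.append({"parameter": "mu", "cluster": j, "component": f"Z{c}", "value": p.mu[j, c]})
        for a in range(p.m):
            for b in range(a, p.m):
                rows.append({"parameter": "Sigma", "cluster": j,
                             "component": f"Z{a}:Z{b}", "value": p.Sigma[j, a, b]})
        rows.append({"parameter": "gamma", "cluster": j, "component": "Y", "value": p.gamma[j]})
        rows.append({"parameter": "sigma2", "cluster": j, "component": "Y", "value": p.sigma2[j]})
    params_path = outdir / "params.csv"
    pd.DataFrame(rows).to_csv(params_path, index=False)

    resp_path = outdir / "responsibilities.csv"
    resp = pd.DataFrame(result.r, columns=[f"cluster{j}" for j in range(p.K)])
    resp.insert(0, "row_id", data.row_ids)
    resp.to_csv(resp_path, index=False)

    imp_path = outdir / "imputed_Z.csv"
    imp = pd.DataFrame(result.Z_imputed, columns=[f"Z{j}" for j in range(p.m)])
    for j in range(p.m):
        imp[f"Z{j}_missing"] = data.mask[:, j]
    imp.insert(0, "row_id", data.row_ids)
    imp.to_csv(imp_path, index=False, na_rep="NA")

    trace_path = outdir / "loglik_trace.csv"
    pd.DataFrame({"iteration": np.arange(len(result.loglik_trace)),
                  "loglik": result.loglik_trace}).to_csv(trace_path, index=False)

    summary = {"schema_version": SUMMARY_SCHEMA_VERSION, **result.summary()}
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))

    return {"params": str(params_path), "responsibilities": str(resp_path),
            "imputed_Z": str(imp_path), "loglik_trace": str(trace_path),
            "summary": str(summary_path)}
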