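"""Reading and writing of expression matrices and sample metadata.

Expression matrices are tab-separated text with probe ids in the first
column and one column per sample (log2 scale).  Metadata is CSV with one
row per sample.  Both loaders validate aggressively and report the file
coordinates of the first offending cell, because silent coercion of a
malformed matrix is the classic way a microarray analysis goes wrong.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

META_COLUMNS = ["sample_id", "tissue", "genotype", "age_days", "batch", "is_tech_rep"]


class ExpressionParseError(ValueError):
    """Raised when an expression TSV cannot be parsed into a clean matrix."""


def read_expression(path) -> pd.DataFrame:
    """Read a probe x sample log2 expression matrix from TSV.

    Returns a float DataFrame with probe ids as the index and sample ids
    as columns.  Ragged rows, duplicate probe/sample ids, missing cells
    and non-numeric cells raise :class:`ExpressionParseError` naming the
    row/column of the problem.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ExpressionParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ExpressionParseError(f"{path}: duplicate probe id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ExpressionParseError(f"{path}: duplicate sample id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | df[col].isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ExpressionParseError(
                f"{path}: non-numeric or missing value at probe "
                f"{df.index[i]!r}, sample {col!r} (data row {i + 1}, column {j + 2})"
            )
        values[:, j] = converted.to_numpy()
    return pd.DataFrame(values, index=df.index.rename("probe_id"), columns=df.columns)


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write an expression matrix as TSV with 6 significant digits."""
    expr.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_meta(path) -> pd.DataFrame:
    """Read sample metadata CSV; returns a DataFrame indexed by sample_id."""
    meta = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    meta = meta.set_index("sample_id")
    meta["is_tech_rep"] = meta["is_tech_rep"].astype(bool)
    return meta


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample_id")


def check_aligned(expr: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Every matrix column must have exactly one metadata row."""
    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
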