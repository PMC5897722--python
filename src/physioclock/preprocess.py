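"""Cross-batch baseline correction, quantile normalization and noise-floor
filtering for log2 expression matrices.

The batch correction assumes a common technical replicate hybridized in
every batch: the per-probe difference between its batch-B and reference
copies estimates the batch-B offset, which is subtracted from every
batch-B column.  Quantile normalization then equalizes the per-sample
distributions, and a lowess fit of the coefficient of variation against
mean expression locates the low-end floor below which signal and noise
are indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class NoiseFloor:
    floor_value: float
    method: str  # "fixed" or "lowess"
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.method not in ("fixed", "lowess"):
            raise ValueError(f"unknown noise-floor method {self.method!r}")


def exclude_samples(expr: pd.DataFrame, meta: pd.DataFrame, exclude):
    """Drop a user-supplied list of outlier samples from matrix and metadata.

    Outlier detection itself is left to the analyst (box plots / PCA);
    this just applies the verdict reproducibly.
    """
    exclude = [s for s in exclude]
    missing = [s for s in exclude if s not in expr.columns]
    if missing:
        raise ValueError(f"exclusion list names unknown samples: {missing}")
    return expr.drop(columns=exclude), meta.drop(index=exclude)


def subtract_batch_baseline(expr: pd.DataFrame, meta: pd.DataFrame,
                            reference_batch=None):
    """Remove per-probe batch offsets using the common technical replicate.

    For each non-reference batch B, the offset vector is the technical
    replicate's batch-B column minus its reference-batch column; it is
    subtracted from every batch-B column.  The now-redundant batch-B
    technical-replicate columns are dropped.  Returns ``(expr, meta)``.
    A single-batch matrix is returned unchanged.
    """
    batches = meta.loc[expr.columns, "batch"]
    batch_levels = list(pd.unique(batches))
    if len(batch_levels) < 2:
        return expr, meta
    if reference_batch is None:
        reference_batch = batch_levels[0]
    tech = meta.loc[expr.columns][meta.loc[expr.columns, "is_tech_rep"]]

    def _tech_col(batch):
        cols = tech.index[tech["batch"] == batch]
        if len(cols) == 0:
            raise ValueError(f"no technical replicate found in batch {batch}")
        return cols[0]

    ref_col = _tech_col(reference_batch)
    expr = expr.copy()
    drop = []
    for b in batch_levels:
        if b == reference_batch:
            continue
        b_col = _tech_col(b)
        delta = expr[b_col] - expr[ref_col]
        cols = [c for c in expr.columns if batches[c] == b]
        expr.loc[:, cols] = expr.loc[:, cols].sub(delta, axis=0)
        drop.append(b_col)
    expr = expr.drop(columns=drop)
    meta = meta.drop(index=drop)
    return expr, meta


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the same distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' sorted values; within-column ranks are preserved, and tied
    values receive the mean of the reference values at their rank
    positions (deterministic, order-independent).
    """
    if expr.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = expr.to_numpy(float)
    reference = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        # average rank -> linear interpolation into the reference vector
        # gives tied entries the mean of the reference at their positions
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, np.arange(len(reference)), reference)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def fit_noise_floor(expr: pd.DataFrame, override: float | None = None,
                    span: float = 0.3, tol_factor: float = 2.0) -> NoiseFloor:
    """Locate the low-end expression value where noise dominates signal.

    Fits a lowess curve of per-probe CV (SD/mean of log2 values) against
    per-probe mean, fits a straight line to the curve over the upper half
    of the mean range, and reports the largest mean at which the lowess
    curve deviates from that line by more than ``tol_factor`` times the
    residual SD of the high-end fit.  With ``override`` the value is
    returned as-is (method="fixed"); diagnostics are populated either way.
    """
    if expr.shape[0] < 10:
        raise ValueError("need at least 10 probes to fit a noise floor")
    means = expr.mean(axis=1).to_numpy()
    sds = expr.std(axis=1, ddof=1).to_numpy()
    if np.allclose(sds, 0) or np.ptp(means) == 0:
        raise ValueError("degenerate (constant) matrix: noise floor undefined")
    cvs = sds / means

    order = np.argsort(means)
    fit = lowess(cvs[order], means[order], frac=span, return_sorted=False)
    diag = pd.DataFrame({"mean": means[order], "cv": cvs[order], "lowess": fit})

    if override is not None:
        return NoiseFloor(float(override), "fixed", diag)

    m = diag["mean"].to_numpy()
    f = diag["lowess"].to_numpy()
    hi = m >= (m.min() + m.max()) / 2.0
    slope, intercept = np.polyfit(m[hi], f[hi], 1)
    resid_sd = np.std(f[hi] - (slope * m[hi] + intercept), ddof=0)
    tol = tol_factor * resid_sd
    # noise inflates CV at the low end: look for an upward, sustained
    # departure of the curve from the high-end line in the lower half
    dev = f - (slope * m + intercept)
    floor = m.min()
    candidates = np.flatnonzero(~hi & (dev > tol))
    for i in candidates[::-1]:  # largest candidate mean first
        if dev[: i + 1].mean() > tol:
            floor = m[i]
            break
    return NoiseFloor(float(floor), "lowess", diag)


def apply_noise_floor(expr: pd.DataFrame, floor: NoiseFloor):
    """Clamp values below the floor and discard never-detected probes.

    Values below the floor are set to the floor; probes whose maximum
    never exceeds it are dropped as non-informative.  Returns
    ``(expr, n_removed)``.
    """
    keep = expr.max(axis=1) > floor.floor_value
    out = expr.loc[keep].clip(lower=floor.floor_value)
    return out, int((~keep).sum())


def preprocess(expr: pd.DataFrame, meta: pd.DataFrame, floor: float | None = 7.5,
               exclude=(), reference_batch=None):
    """Full preprocessing chain: exclusions, batch baseline subtraction,
    quantile normalization, noise-floor clamping/filtering.

    Returns ``(expr, meta, NoiseFloor, n_probes_removed)``.
    """
    if exclude:
        expr, meta = exclude_samples(expr, meta, exclude)
    expr, meta = subtract_batch_baseline(expr, meta, reference_batch)
    expr = quantile_normalize(expr)
    nf = fit_noise_floor(expr, override=floor)
    expr, n_removed = apply_noise_floor(expr, nf)
    return expr, meta, nf, n_removed
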