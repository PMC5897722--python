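"""Aging-gene discovery by polyserial correlation with a permutation null.

Age class is treated as an ordinal variable assumed to discretize a
latent standard normal at thresholds set by the class proportions.  The
polyserial correlation between a probe's expression and that latent
variable measures how linearly expression tracks age.  Significance
cutoffs come from re-estimating the correlations under randomized age
labels: probes whose true-label estimate falls more than two standard
deviations from the mean of the pooled null estimates are flagged
aging-related (two-sided, nominally P < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class PermNull:
    B: int
    null_mean: float
    null_sd: float
    lo: float
    hi: float
    seed: int

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("degenerate permutation null (lo >= hi)")


def _ordinal_codes(y, use_ranks: bool = True) -> np.ndarray:
    """Code ordinal classes as 1..K (default) or as their raw values."""
    y = np.asarray(y)
    levels = np.unique(y)
    if use_ranks:
        lookup = {v: i + 1 for i, v in enumerate(levels)}
        return np.array([lookup[v] for v in y], dtype=float)
    return y.astype(float)


def _thresholds(y) -> np.ndarray:
    """Latent-normal thresholds from cumulative class proportions."""
    y = np.asarray(y)
    levels, counts = np.unique(y, return_counts=True)
    cum = np.cumsum(counts)[:-1] / y.size
    return stats.norm.ppf(cum)


def polyserial_rho(x, y, use_ranks: bool = True) -> float:
    """Two-step polyserial correlation of a continuous x with ordinal y.

    Estimator: ``rho = r_xy * s_y / sum_k phi(tau_k)`` where ``r_xy`` is
    the Pearson correlation of x with the integer-coded classes, ``s_y``
    the sample SD of the codes, and ``tau_k`` the latent thresholds from
    the cumulative class proportions.  The result is clipped to [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    codes = _ordinal_codes(y, use_ranks)
    if np.unique(codes).size < 2:
        raise ValueError("need at least 2 distinct ordinal classes")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; polyserial correlation undefined")
    r = stats.pearsonr(x, codes).statistic
    s_y = np.std(codes, ddof=1)
    phi_sum = stats.norm.pdf(_thresholds(codes)).sum()
    return float(np.clip(r * s_y / phi_sum, -1.0, 1.0))


def polyserial_rho_matrix(values: np.ndarray, y, use_ranks: bool = True) -> np.ndarray:
    """Vectorized two-step estimator over the rows of a probe x sample array."""
    codes = _ordinal_codes(y, use_ranks)
    s_y = np.std(codes, ddof=1)
    phi_sum = stats.norm.pdf(_thresholds(codes)).sum()
    xc = values - values.mean(axis=1, keepdims=True)
    yc = codes - codes.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = xc @ yc / denom
    return np.clip(r * s_y / phi_sum, -1.0, 1.0)


def polyserial_rho_ml(x, y) -> float:
    """Maximum-likelihood polyserial correlation (independent slow route).

    Maximizes the joint likelihood of (x, y) under the latent bivariate
    normal model, with the marginal of x taken as normal at its sample
    moments and the thresholds fixed at their empirical estimates.  Used
    as a cross-check oracle for the two-step estimator.
    """
    x = np.asarray(x, dtype=float)
    codes = _ordinal_codes(y).astype(int)
    tau = np.concatenate([[-np.inf], _thresholds(codes), [np.inf]])
    z = (x - x.mean()) / x.std(ddof=1)
    k = codes - codes.min()  # 0-based class index

    def negloglik(rho):
        rho = np.clip(rho, -0.999, 0.999)
        s = np.sqrt(1.0 - rho * rho)
        upper = stats.norm.cdf((tau[k + 1] - rho * z) / s)
        lower = stats.norm.cdf((tau[k] - rho * z) / s)
        p = np.clip(upper - lower, 1e-300, None)
        return -(np.log(p).sum() + stats.norm.logpdf(z).sum())

    res = optimize.minimize_scalar(negloglik, bounds=(-0.999, 0.999),
                                   method="bounded")
    return float(res.x)


def build_perm_null(expr: pd.DataFrame, ages, B: int = 20, seed: int = 0,
                    use_ranks: bool = True, per_probe: bool = False) -> PermNull:
    """Null distribution of polyserial estimates under randomized age.

    For each of B rounds the age labels are permuted over samples (one
    permutation shared by all probes, preserving inter-gene correlation;
    ``per_probe=True`` permutes independently per probe) and the
    estimator is run for every probe.  All ``B * n_probes`` estimates are
    pooled; cutoffs are mean +/- 2 SD.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    values = expr.to_numpy(float)
    ages = np.asarray(ages)
    pooled = np.empty((B, values.shape[0]))
    for b in range(B):
        if per_probe:
            idx = np.argsort(rng.random((values.shape[0], ages.size)), axis=1)
            shuffled = values[np.arange(values.shape[0])[:, None], idx]
            pooled[b] = polyserial_rho_matrix(shuffled, ages, use_ranks)
        else:
            perm = rng.permutation(ages.size)
            pooled[b] = polyserial_rho_matrix(values, ages[perm], use_ranks)
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    return PermNull(B=B, null_mean=mean, null_sd=sd,
                    lo=mean - 2.0 * sd, hi=mean + 2.0 * sd, seed=seed)


def select_aging_genes(expr: pd.DataFrame, ages, null: PermNull,
                       use_ranks: bool = True) -> pd.DataFrame:
    """Flag probes whose polyserial estimate falls outside the null band.

    Returns a table with columns ``rho``, ``direction`` ("up"/"down")
    and ``is_aging``, indexed by probe id.
    """
    rho = polyserial_rho_matrix(expr.to_numpy(float), ages, use_ranks)
    is_aging = (rho < null.lo) | (rho > null.hi)
    return pd.DataFrame(
        {
            "rho": rho,
            "direction": np.where(rho >= 0, "up", "down"),
            "is_aging": is_aging,
        },
        index=expr.index,
    )
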