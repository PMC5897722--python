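"""Genotype-affected probe calls and gene-set comparison statistics.

A probe counts as affected for a class contrast when it clears three
gates in order: one-way ANOVA across sample classes with
Benjamini-Hochberg correction (q < 0.05), a Tukey-HSD post hoc on the
specific pair (p < 0.05), and an absolute mean difference of at least
1.5-fold (|delta log2| >= log2 1.5).  Probes failing the ANOVA gate are
not Tukey-tested.  Overlaps between probe sets are assessed with a
Yates-corrected chi-square on the 2x2 membership table, and shared
effects with Pearson correlation of fold changes plus the fraction of
sign-concordant probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FOLD_LOG2 = np.log2(1.5)

_TUKEY_GRID_CACHE: dict = {}


def tukey_sf(q, k: int, df: int) -> np.ndarray:
    """Survival function of the studentized range, interpolated.

    ``scipy.stats.studentized_range.sf`` integrates numerically per point
    (~10 ms each), which is prohibitive across thousands of probes.  The
    exact sf is evaluated once on a fixed grid per (k, df) and monotone
    cubic interpolation of its logarithm serves all queries; beyond the
    grid the tail is effectively zero.  Accuracy is ~1e-4 in p, ample for
    a 0.05 gate.
    """
    key = (int(k), int(df))
    if key not in _TUKEY_GRID_CACHE:
        grid = np.linspace(0.0, 15.0, 151)
        logsf = np.log(np.clip(stats.studentized_range.sf(grid[1:], k, df),
                               1e-300, 1.0))
        from scipy.interpolate import PchipInterpolator
        _TUKEY_GRID_CACHE[key] = PchipInterpolator(grid[1:], logsf,
                                                   extrapolate=True)
    q = np.asarray(q, dtype=float)
    out = np.exp(_TUKEY_GRID_CACHE[key](np.clip(q, 1e-9, 15.0)))
    out = np.where(q > 15.0, 0.0, np.clip(out, 0.0, 1.0))
    return out


def sample_classes(meta: pd.DataFrame) -> pd.Series:
    """Label each sample by its genotype x age cell, e.g. ``null@10``."""
    return (meta["genotype"].astype(str) + "@"
            + meta["age_days"].map(lambda a: f"{a:g}"))


@dataclass
class DEResult:
    """Per-probe ANOVA/Tukey/fold-change results for a set of contrasts.

    ``table`` has columns ``anova_p``, ``anova_q`` and, per contrast
    ``(a, b)``, ``tukey_p[a|b]``, ``log2fc[a|b]`` (mean of b minus mean
    of a) and ``affected[a|b]``.
    """

    table: pd.DataFrame
    contrasts: list

    @staticmethod
    def key(contrast) -> str:
        a, b = contrast
        return f"{a}|{b}"

    def affected_probes(self, contrast=None) -> pd.Index:
        if contrast is None:
            cols = [f"affected[{self.key(c)}]" for c in self.contrasts]
            mask = self.table[cols].any(axis=1)
        else:
            mask = self.table[f"affected[{self.key(contrast)}]"]
        return self.table.index[mask]

    def log2fc(self, contrast) -> pd.Series:
        return self.table[f"log2fc[{self.key(contrast)}]"]


def call_affected(expr: pd.DataFrame, classes: pd.Series, contrasts=None,
                  alpha: float = 0.05, fold: float = 1.5) -> DEResult:
    """ANOVA + BH + Tukey-HSD + fold-change gating over all probes.

    ``classes`` assigns each matrix column to a sample class; the ANOVA
    factor is that class.  ``contrasts`` is a list of (reference, test)
    class pairs; default is every pair.  Each class needs >= 2 replicates.
    """
    classes = classes.loc[expr.columns]
    levels = list(pd.unique(classes))
    if len(levels) < 2:
        raise ValueError("need at least 2 sample classes")
    values = expr.to_numpy(float)
    groups = {lv: values[:, (classes == lv).to_numpy()] for lv in levels}
    for lv, g in groups.items():
        if g.shape[1] < 2:
            raise ValueError(f"class {lv!r} has fewer than 2 replicates")
    if contrasts is None:
        contrasts = [(levels[i], levels[j])
                     for i in range(len(levels)) for j in range(i + 1, len(levels))]
    contrasts = [tuple(c) for c in contrasts]

    with np.errstate(invalid="ignore", divide="ignore"):
        f_res = stats.f_oneway(*groups.values(), axis=1)
    anova_p = np.nan_to_num(f_res.pvalue, nan=1.0)
    anova_q = multipletests(anova_p, method="fdr_bh")[1]

    k = len(levels)
    n_total = values.shape[1]
    df_w = n_total - k
    means = {lv: g.mean(axis=1) for lv, g in groups.items()}
    sse = sum(((g - means[lv][:, None]) ** 2).sum(axis=1)
              for lv, g in groups.items())
    mse = sse / df_w

    table = pd.DataFrame({"anova_p": anova_p, "anova_q": anova_q},
                         index=expr.index)
    gate = anova_q < alpha
    log_fold = np.log2(fold)
    for a, b in contrasts:
        key = f"{a}|{b}"
        fc = means[b] - means[a]
        n_a, n_b = groups[a].shape[1], groups[b].shape[1]
        # Tukey-Kramer studentized range statistic
        se = np.sqrt(mse / 2.0 * (1.0 / n_a + 1.0 / n_b))
        tukey_p = np.full(values.shape[0], np.nan)
        if gate.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                q = np.abs(fc[gate]) / se[gate]
                tukey_p[gate] = tukey_sf(q, k, df_w)
        affected = gate & (np.nan_to_num(tukey_p, nan=1.0) < alpha) \
            & (np.abs(fc) >= log_fold)
        table[f"tukey_p[{key}]"] = tukey_p
        table[f"log2fc[{key}]"] = fc
        table[f"affected[{key}]"] = affected
    return DEResult(table=table, contrasts=contrasts)


@dataclass
class OverlapStats:
    n_universe: int
    n_A: int
    n_B: int
    n_AB: int
    chi2_yates: float
    p_value: float


def overlap_test(setA, setB, universe_size: int) -> OverlapStats:
    """Yates-corrected chi-square for the overlap of two probe sets.

    Builds the 2x2 in/out-of-A by in/out-of-B table over a universe of
    ``universe_size`` probes and tests independence (1 df, two-sided).
    """
    setA, setB = set(setA), set(setB)
    if universe_size <= 0:
        raise ValueError("universe must be non-empty")
    if len(setA | setB) > universe_size:
        raise ValueError("sets exceed the stated universe")
    n_ab = len(setA & setB)
    a = n_ab
    b = len(setA) - n_ab
    c = len(setB) - n_ab
    d = universe_size - len(setA | setB)
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=True)
    return OverlapStats(n_universe=universe_size, n_A=len(setA), n_B=len(setB),
                        n_AB=n_ab, chi2_yates=float(chi2), p_value=float(p))


def concordance(effectsA: pd.Series, effectsB: pd.Series):
    """Agreement of fold changes over the shared probe set.

    Returns ``(r2, pct_concordant)``: squared Pearson correlation of the
    two log2 fold-change vectors and the percentage of probes whose fold
    changes share a sign.
    """
    shared = effectsA.index.intersection(effectsB.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared probes; concordance undefined")
    a = effectsA.loc[shared].to_numpy(float)
    b = effectsB.loc[shared].to_numpy(float)
    r = stats.pearsonr(a, b).statistic
    pct = 100.0 * float(np.mean(np.sign(a) == np.sign(b)))
    return float(r * r), pct


def classify_rescue(de_null: DEResult, contrast_null,
                    de_rescue: DEResult, contrast_rescue) -> pd.DataFrame:
    """Classify null-affected probes as fully/partially/not rescued.

    A probe affected in the null-vs-control contrast is *fully* rescued
    if it is no longer affected in rescue-vs-control, *partially* rescued
    if still affected but its fold change has moved toward control
    (smaller magnitude than in the null), otherwise *none*.
    """
    null_affected = de_null.affected_probes(contrast_null)
    fc_n = de_null.log2fc(contrast_null)
    missing = null_affected.difference(de_rescue.table.index)
    if len(missing) > 0:
        warnings.warn(f"{len(missing)} null-affected probes absent from the "
                      "rescue table; classified as not rescued")
    status = pd.Series("none", index=null_affected, name="status")
    present = null_affected.intersection(de_rescue.table.index)
    fc_r = de_rescue.log2fc(contrast_rescue).loc[present]
    rescued_affected = de_rescue.table.loc[
        present, f"affected[{de_rescue.key(contrast_rescue)}]"]
    toward = fc_r.abs() < fc_n.loc[present].abs()
    status.loc[present[~rescued_affected.to_numpy(bool)]] = "full"
    partial = rescued_affected.to_numpy(bool) & toward.to_numpy(bool)
    status.loc[present[partial]] = "partial"
    return status.to_frame()


def rescue_summary(status: pd.DataFrame) -> dict:
    n = len(status)
    counts = status["status"].value_counts()
    full = int(counts.get("full", 0))
    partial = int(counts.get("partial", 0))
    pct = 100.0 * (full + partial) / n if n else float("nan")
    return {"n_null_affected": n, "n_full": full, "n_partial": partial,
            "pct_rescued": pct}
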