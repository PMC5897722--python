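"""Profile similarity of mutant samples to controls of each age.

Over the probes both aging-related and mutant-affected, every mutant
sample is Pearson-correlated with every control sample; the correlations
are grouped by control age and compared across ages with one-way ANOVA
plus Tukey post hoc.  A mutant whose transcriptome has aged faster than
its calendar suggests correlates best with older controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def intersect_probe_set(aging_table: pd.DataFrame, de_result,
                        contrast=None) -> pd.Index:
    """Probes flagged both aging-related and genotype-affected."""
    aging_ids = aging_table.index[aging_table["is_aging"]]
    affected_ids = de_result.affected_probes(contrast)
    shared = aging_ids.intersection(affected_ids)
    if len(shared) == 0:
        raise ValueError("aging and affected probe sets are disjoint; "
                         "profile correlation is undefined")
    return shared


@dataclass
class SimilarityResult:
    probe_set: list
    pairs: pd.DataFrame          # mutant_sample, control_sample, control_age, r
    per_age: pd.DataFrame        # mean, sem, n per control age
    anova_p: float | None = None
    tukey_p: dict | None = None


def profile_correlations(expr: pd.DataFrame, meta: pd.DataFrame, probe_set,
                         mutant_samples, control_samples,
                         on_means: bool = False) -> SimilarityResult:
    """Correlate each mutant profile with each control profile.

    With ``on_means`` the mutant group's mean profile (rather than each
    replicate) is correlated against each control sample.  Requires at
    least 3 probes in ``probe_set``.
    """
    probe_set = list(probe_set)
    if len(probe_set) < 3:
        raise ValueError("need at least 3 probes for profile correlation")
    sub = expr.loc[probe_set]
    mutants = list(mutant_samples)
    controls = list(control_samples)
    if on_means:
        mean_profile = sub[mutants].mean(axis=1)
        mut_profiles = {"group_mean": mean_profile.to_numpy(float)}
    else:
        mut_profiles = {m: sub[m].to_numpy(float) for m in mutants}

    rows = []
    for m, mvec in mut_profiles.items():
        for c in controls:
            r = stats.pearsonr(mvec, sub[c].to_numpy(float)).statistic
            rows.append((m, c, float(meta.loc[c, "age_days"]), float(r)))
    pairs = pd.DataFrame(rows, columns=["mutant_sample", "control_sample",
                                        "control_age", "r"])

    per_age = pairs.groupby("control_age")["r"].agg(["mean", "sem", "count"]) \
        .rename(columns={"count": "n"})
    result = SimilarityResult(probe_set=probe_set, pairs=pairs, per_age=per_age)

    by_age = [g["r"].to_numpy() for _, g in pairs.groupby("control_age")]
    if len(by_age) > 1 and all(len(g) >= 2 for g in by_age):
        result.anova_p = float(stats.f_oneway(*by_age).pvalue)
        tk = stats.tukey_hsd(*by_age)
        ages = sorted(pairs["control_age"].unique())
        result.tukey_p = {
            f"{ages[i]:g}|{ages[j]:g}": float(tk.pvalue[i, j])
            for i in range(len(ages)) for j in range(i + 1, len(ages))
        }
    return result
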