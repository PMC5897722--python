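"""Synthetic expression data with planted aging structure.

The generator emulates the design of a two-batch microarray aging study in
an insect model: control samples collected at four ages (3, 10, 30 and 45
days), ~5 biological replicates per cell, a fraction of probes with
monotone (linear on the log2 scale) age trends split evenly between
increasing and decreasing, homoscedastic Gaussian noise, a second
hybridization batch with per-probe offsets anchored by a common technical
replicate, and mutant samples whose aging-probe trends are evaluated at an
accelerated effective age ``a * chronological_age``.

Low-end censoring at the detection floor is deliberately NOT applied here;
the preprocessing stage owns that rule, so matrices are emitted raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FOLD_LOG2 = np.log2(1.5)


@dataclass
class SimDesign:
    """Parameters of the simulated study.

    ``slope_loc``/``slope_sd`` give the location and spread of the
    magnitude of per-gene log2-per-day slopes; signs are balanced half
    up, half down.  ``accel_factor`` multiplies chronological age to give
    the effective age at which mutant aging-probe trends are evaluated.
    """

    n_probes: int = 2000
    frac_aging: float = 0.2
    ages: tuple = (3, 10, 30, 45)
    reps_per_cell: int = 5
    slope_loc: float = 0.03
    slope_sd: float = 0.01
    noise_sd: float = 0.25
    batch_offset_sd: float = 0.3
    floor_true: float = 7.5
    accel_factor: float = 1.3
    n_mutant_specific: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_aging <= 1.0:
            raise ValueError("frac_aging must be in [0, 1]")
        ages = tuple(self.ages)
        if len(ages) < 2 or any(a <= 0 for a in ages) or list(ages) != sorted(set(ages)):
            raise ValueError("ages must be strictly increasing and positive")
        self.ages = ages
        if self.accel_factor <= 0:
            raise ValueError("accel_factor must be positive")
        if self.reps_per_cell < 2:
            raise ValueError("reps_per_cell must be >= 2 (variance undefined below)")


@dataclass
class SimTruth:
    """Ground truth of one simulated study, for recovery tests."""

    baselines: pd.Series
    slopes: pd.Series  # log2 units / day; 0 for non-aging probes
    aging_probe_ids: list
    mutant_specific_ids: list
    mutant_offsets: pd.Series  # log2 shifts for mutant-specific probes
    batch_offsets: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self):
        overlap = set(self.aging_probe_ids) & set(self.mutant_specific_ids)
        if overlap:
            raise ValueError("aging and mutant-specific probe sets must be disjoint")


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"probe_{i:05d}" for i in range(n)], name="probe_id")


def _make_truth(design: SimDesign, rng: np.random.Generator) -> SimTruth:
    probes = _probe_ids(design.n_probes)
    n_aging = int(round(design.frac_aging * design.n_probes))
    order = rng.permutation(design.n_probes)
    aging_idx = order[:n_aging]
    n_mut = min(design.n_mutant_specific, design.n_probes - n_aging)
    mutant_idx = order[n_aging:n_aging + n_mut]

    baselines = pd.Series(rng.uniform(8.5, 13.0, design.n_probes), index=probes)
    slopes = pd.Series(0.0, index=probes)
    mags = np.abs(rng.normal(design.slope_loc, design.slope_sd, n_aging))
    signs = np.ones(n_aging)
    signs[: n_aging // 2] = -1.0
    rng.shuffle(signs)
    slopes.iloc[aging_idx] = mags * signs

    mutant_offsets = pd.Series(0.0, index=probes)
    # margin above the 1.5-fold gate so planted probes are reliably
    # discoverable at noise_sd 0.25 with 5 replicates per group
    mut_mag = FOLD_LOG2 + 0.65 + np.abs(rng.normal(0.0, 0.25, n_mut))
    mut_sign = rng.choice([-1.0, 1.0], n_mut)
    mutant_offsets.iloc[mutant_idx] = mut_mag * mut_sign

    return SimTruth(
        baselines=baselines,
        slopes=slopes,
        aging_probe_ids=list(probes[np.sort(aging_idx)]),
        mutant_specific_ids=list(probes[np.sort(mutant_idx)]),
        mutant_offsets=mutant_offsets,
    )


def _sample_block(truth: SimTruth, effective_ages, noise_sd, rng,
                  extra_offsets=None) -> np.ndarray:
    """Draw one column per entry of effective_ages from the trend model."""
    mu = truth.baselines.to_numpy()[:, None] + np.outer(
        truth.slopes.to_numpy(), np.asarray(effective_ages, dtype=float)
    )
    if extra_offsets is not None:
        mu = mu + np.asarray(extra_offsets, dtype=float)[:, None]
    return mu + rng.normal(0.0, noise_sd, mu.shape)


def generate_control_timecourse(design: SimDesign, drop_day3_outlier: bool = False):
    """Simulate the control time course.

    Returns ``(expr, meta, truth)``.  Aging probes follow expectation
    ``b0 + slope * age``; all others are flat.  With ``drop_day3_outlier``
    the first age class gets one fewer replicate, mirroring removal of a
    cohort-level outlier sample.

    >>> expr, meta, truth = generate_control_timecourse(SimDesign(seed=1))
    >>> expr.shape[1] == len(meta)
    True
    """
    rng = np.random.default_rng([design.seed, 101])
    truth = _make_truth(design, rng)

    ages, sample_ids = [], []
    for age in design.ages:
        reps = design.reps_per_cell
        if drop_day3_outlier and age == design.ages[0]:
            reps -= 1
        for r in range(reps):
            ages.append(age)
            sample_ids.append(f"ctrl_d{age}_r{r + 1}")
    values = _sample_block(truth, ages, design.noise_sd, rng)
    expr = pd.DataFrame(values, index=truth.baselines.index, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "tissue": "head",
            "genotype": "control",
            "age_days": ages,
            "batch": 1,
            "is_tech_rep": False,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return expr, meta, truth


def generate_mutant_samples(design: SimDesign, truth: SimTruth, chron_age: float,
                            genotype: str = "null", n_reps: int | None = None,
                            accel_factor: float | None = None,
                            offset_scale: float = 1.0, seed_tag: int = 202):
    """Simulate mutant replicates at one chronological age.

    Aging probes are evaluated at the effective age ``a * chron_age``;
    mutant-specific probes additionally receive their planted offsets
    (scaled by ``offset_scale``; a rescue genotype uses a small scale).
    Returns ``(expr, meta)``.
    """
    a = design.accel_factor if accel_factor is None else accel_factor
    if a <= 0:
        raise ValueError("accel_factor must be positive")
    n_reps = design.reps_per_cell if n_reps is None else n_reps
    rng = np.random.default_rng([design.seed, seed_tag, int(chron_age * 1000)])
    eff = [a * chron_age] * n_reps
    values = _sample_block(
        truth, eff, design.noise_sd, rng,
        extra_offsets=truth.mutant_offsets.to_numpy() * offset_scale,
    )
    ids = [f"{genotype}_d{chron_age:g}_r{r + 1}" for r in range(n_reps)]
    expr = pd.DataFrame(values, index=truth.baselines.index, columns=ids)
    meta = pd.DataFrame(
        {
            "tissue": "head",
            "genotype": genotype,
            "age_days": float(chron_age),
            "batch": 1,
            "is_tech_rep": False,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return expr, meta


def generate_batches(expr: pd.DataFrame, meta: pd.DataFrame, design: SimDesign,
                     batch2_samples=(), tech_rep: str | None = None,
                     truth: SimTruth | None = None):
    """Split samples into two hybridization batches with per-probe offsets.

    Columns named in ``batch2_samples`` are shifted by per-probe offsets
    drawn from N(0, batch_offset_sd).  The ``tech_rep`` sample (which must
    be outside batch 2) is re-hybridized into batch 2 as a new column
    ``<id>__b2`` differing from the original only by the offsets plus
    fresh noise.  With no batch-2 samples the inputs are returned
    unchanged.  Offsets are recorded on ``truth`` when given.
    """
    batch2_samples = list(batch2_samples)
    if not batch2_samples:
        return expr, meta
    if tech_rep is None:
        raise ValueError("a technical replicate sample must be designated")
    if tech_rep not in expr.columns:
        raise ValueError(f"technical replicate {tech_rep!r} not in matrix")
    if tech_rep in batch2_samples:
        raise ValueError("technical replicate must belong to the reference batch")

    rng = np.random.default_rng([design.seed, 303])
    offsets = pd.Series(rng.normal(0.0, design.batch_offset_sd, expr.shape[0]),
                        index=expr.index)
    expr = expr.copy()
    meta = meta.copy()
    expr.loc[:, batch2_samples] = expr.loc[:, batch2_samples].add(offsets, axis=0)
    meta.loc[batch2_samples, "batch"] = 2

    rep2 = f"{tech_rep}__b2"
    expr[rep2] = (expr[tech_rep] + offsets
                  + rng.normal(0.0, design.noise_sd, expr.shape[0]))
    meta.loc[tech_rep, "is_tech_rep"] = True
    rep2_row = meta.loc[[tech_rep]].rename(index={tech_rep: rep2})
    rep2_row["batch"] = 2
    meta = pd.concat([meta, rep2_row])

    if truth is not None:
        truth.batch_offsets = offsets
    return expr, meta


def simulate_study(design: SimDesign, drop_day3_outlier: bool = True,
                   genotypes: dict | None = None,
                   rescue_offset_scale: float = 0.2):
    """Simulate the full two-batch study: control time course plus day-10
    mutants, with the rescue genotype in a second batch.

    ``genotypes`` maps genotype name to acceleration factor; default
    mirrors a null and an overexpression line at the design's factor and
    a rescue line back at factor 1 with mutant-specific offsets mostly
    reverted.  Returns ``(expr, meta, truth)``.
    """
    if genotypes is None:
        genotypes = {"null": design.accel_factor, "OE": design.accel_factor,
                     "rescue": 1.0}
    expr, meta, truth = generate_control_timecourse(design, drop_day3_outlier)
    chron = design.ages[1] if len(design.ages) > 1 else design.ages[0]
    batch2 = []
    for tag, (gt, a) in enumerate(genotypes.items()):
        scale = rescue_offset_scale if gt == "rescue" else 1.0
        e, m = generate_mutant_samples(design, truth, chron, genotype=gt,
                                       accel_factor=a, offset_scale=scale,
                                       seed_tag=400 + tag)
        expr = pd.concat([expr, e], axis=1)
        meta = pd.concat([meta, m])
        if gt == "rescue":
            batch2.extend(e.columns)
    tech_rep = f"ctrl_d{chron}_r1"
    expr, meta = generate_batches(expr, meta, design, batch2_samples=batch2,
                                  tech_rep=tech_rep, truth=truth)
    return expr, meta, truth
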