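"""End-to-end orchestration: simulate -> preprocess -> aging genes ->
differential expression -> clock -> similarity -> summary report.

All randomness flows from one seed, fanned out per stage as
``crc32(stage_name) XOR seed (mod 2^31)`` so stages can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .aging import build_perm_null, select_aging_genes
from .clock import fit_age_clock, loo_knn_select, predict_physio_age, \
    summarize_acceleration
from .diffexpr import call_affected, concordance, classify_rescue, \
    overlap_test, rescue_summary, sample_classes
from .preprocess import preprocess
from .similarity import intersect_probe_set, profile_correlations
from .simulate import SimDesign, simulate_study


def stage_seed(seed: int, stage: str) -> int:
    return (zlib.crc32(stage.encode()) ^ seed) % (2 ** 31)


@dataclass
class PipelineConfig:
    seed: int = 0
    design: SimDesign = field(default_factory=SimDesign)
    floor: float | None = 7.5
    exclude: tuple = ()
    B: int = 20
    k: int = 3
    alpha: float = 0.05
    fold: float = 1.5
    var_explained: float = 0.95
    outdir: str | None = None

    def config_hash(self) -> str:
        d = asdict(self)
        d["design"]["ages"] = list(d["design"]["ages"])
        d["exclude"] = list(d["exclude"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study and return the summary report.

    When ``config.outdir`` is set, per-stage TSV/JSON artifacts are
    written there alongside ``summary.json``.
    """
    design = SimDesign(**{**asdict(config.design),
                          "seed": stage_seed(config.seed, "simulate")})
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                     "stages": {}}

    # 1. simulate
    expr, meta, truth = simulate_study(design)
    summary["stages"]["simulate"] = {
        "n_probes": int(expr.shape[0]), "n_samples": int(expr.shape[1]),
        "n_aging_true": len(truth.aging_probe_ids),
    }

    # 2. preprocess
    expr, meta, floor, n_removed = preprocess(
        expr, meta, floor=config.floor, exclude=config.exclude)
    summary["stages"]["preprocess"] = {
        "floor": floor.floor_value, "floor_method": floor.method,
        "probes_removed": n_removed, "n_probes": int(expr.shape[0]),
    }

    # 3. aging genes (controls only)
    ctrl = meta.index[meta["genotype"] == "control"]
    ctrl_expr = expr[ctrl]
    ctrl_ages = meta.loc[ctrl, "age_days"]
    null = build_perm_null(ctrl_expr, ctrl_ages, B=config.B,
                           seed=stage_seed(config.seed, "aging"))
    aging_table = select_aging_genes(ctrl_expr, ctrl_ages, null)
    summary["stages"]["aging"] = {
        "n_aging": int(aging_table["is_aging"].sum()),
        "null_lo": null.lo, "null_hi": null.hi, "B": null.B,
    }

    # 4. differential expression at the shared chronological age
    chron = design.ages[1]
    classes = sample_classes(meta)
    de = call_affected(expr, classes, alpha=config.alpha, fold=config.fold)
    ctrl_class = f"control@{chron:g}"
    de_block: dict = {}
    mut_contrasts = {}
    for gt in pd.unique(meta["genotype"]):
        if gt == "control":
            continue
        contrast = (ctrl_class, f"{gt}@{chron:g}")
        mut_contrasts[gt] = contrast
        de_block[gt] = {"n_affected": int(len(de.affected_probes(contrast)))}
    if {"null", "OE"} <= set(mut_contrasts):
        a = de.affected_probes(mut_contrasts["null"])
        b = de.affected_probes(mut_contrasts["OE"])
        ov = overlap_test(a, b, expr.shape[0])
        de_block["null_OE_overlap"] = {
            "n_AB": ov.n_AB, "chi2_yates": ov.chi2_yates, "p": ov.p_value}
        shared = a.intersection(b)
        if len(shared) >= 3:
            r2, pct = concordance(de.log2fc(mut_contrasts["null"]).loc[shared],
                                  de.log2fc(mut_contrasts["OE"]).loc[shared])
            de_block["null_OE_concordance"] = {"r2": r2, "pct_concordant": pct}
    if {"null", "rescue"} <= set(mut_contrasts):
        status = classify_rescue(de, mut_contrasts["null"],
                                 de, mut_contrasts["rescue"])
        de_block["rescue"] = rescue_summary(status)
    summary["stages"]["diffexpr"] = de_block

    # 5. clock: LOO classifier discovery, fit on controls, predict all
    classifiers = loo_knn_select(ctrl_expr, ctrl_ages, k=config.k,
                                 alpha=config.alpha, fold=config.fold)
    clock = fit_age_clock(ctrl_expr, ctrl_ages.astype(float), classifiers,
                          var_explained=config.var_explained)
    preds = predict_physio_age(clock, expr, meta["age_days"].astype(float))
    accel = summarize_acceleration(preds, meta["genotype"])
    summary["stages"]["clock"] = {
        "n_classifiers": int(len(classifiers.probe_ids)),
        "loo_accuracy": classifiers.loo_accuracy,
        "selected_pcs": list(clock.selected_pcs),
        "acceleration": accel,
    }

    # 6. similarity of mutants to each control age
    sim_block = {}
    for gt in ("null", "OE"):
        if gt not in mut_contrasts:
            continue
        try:
            probe_set = intersect_probe_set(aging_table, de,
                                            mut_contrasts[gt])
            res = profile_correlations(
                expr, meta, probe_set,
                mutant_samples=meta.index[meta["genotype"] == gt],
                control_samples=ctrl)
        except ValueError as exc:
            sim_block[gt] = {"error": str(exc)}
            continue
        sim_block[gt] = {
            "n_probes": len(probe_set),
            "n_pairs": int(len(res.pairs)),
            "per_age_mean_r": {f"{a:g}": float(m) for a, m in
                               res.per_age["mean"].items()},
        }
    summary["stages"]["similarity"] = sim_block

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_expression(expr, out / "normed.tsv")
        io.write_meta(meta, out / "meta.csv")
        aging_table.to_csv(out / "aging_table.tsv", sep="\t")
        de.table.to_csv(out / "de.tsv", sep="\t")
        clock.to_json(out / "clock.json")
        preds.to_csv(out / "predictions.tsv", sep="\t")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
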