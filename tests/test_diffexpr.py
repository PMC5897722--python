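"""Affected-probe calls, overlap/concordance statistics, rescue rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from physioclock import (DEResult, SimDesign, call_affected, classify_rescue,
                         concordance, generate_control_timecourse,
                         generate_mutant_samples, overlap_test,
                         rescue_summary, sample_classes)
from physioclock.diffexpr import tukey_sf


def _yates_closed_form(a, b, c, d):
    n = a + b + c + d
    num = max(0.0, abs(a * d - b * c) - n / 2)  # correction clamps at 0
    return n * num ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def _mutant_vs_control(seed=0, shift=1.0, n_shifted=40, n_probes=500,
                       noise_sd=0.25, n=5):
    rng = np.random.default_rng(seed)
    probes = pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id")
    base = rng.uniform(8, 12, n_probes)
    ctrl = base[:, None] + rng.normal(0, noise_sd, (n_probes, n))
    mut = base[:, None] + rng.normal(0, noise_sd, (n_probes, n))
    planted = probes[:n_shifted]
    mut[:n_shifted] += shift * rng.choice([-1, 1], n_shifted)[:, None]
    expr = pd.DataFrame(np.hstack([ctrl, mut]), index=probes,
                        columns=[f"c{i}" for i in range(n)]
                        + [f"m{i}" for i in range(n)])
    classes = pd.Series(["control"] * n + ["mutant"] * n, index=expr.columns)
    return expr, classes, planted


class TestCallAffected:
    def test_planted_shift_recovered(self):
        # 1.25 log2 at noise 0.25 and n=5 clears the BH+Tukey+fold gates
        # with per-probe power ~1; 1.0 log2 would leave ~10% misses
        expr, classes, planted = _mutant_vs_control(seed=1, shift=1.25)
        de = call_affected(expr, classes)
        hit = de.affected_probes(("control", "mutant"))
        assert len(set(planted) & set(hit)) >= len(planted) - 1
        false_hits = set(hit) - set(planted)
        assert len(false_hits) <= 0.05 * len(hit)

    def test_null_flags_nothing(self):
        expr, classes, _ = _mutant_vs_control(seed=2, n_shifted=0)
        de = call_affected(expr, classes)
        assert len(de.affected_probes(("control", "mutant"))) == 0

    def test_bh_never_adds_significance(self):
        expr, classes, _ = _mutant_vs_control(seed=3)
        de = call_affected(expr, classes)
        assert ((de.table["anova_q"] < 0.05).sum()
                <= (de.table["anova_p"] < 0.05).sum())
        assert (de.table["anova_q"] >= de.table["anova_p"] - 1e-12).all()

    def test_affected_monotone_in_fold_change(self):
        """Scaling a probe's mean shift up cannot un-flag it."""
        expr, classes, planted = _mutant_vs_control(seed=4, shift=0.7)
        de1 = call_affected(expr, classes)
        key = "affected[control|mutant]"
        expr2 = expr.copy()
        mut_cols = classes.index[classes == "mutant"]
        fc = de1.log2fc(("control", "mutant"))
        expr2.loc[planted, mut_cols] = (
            expr2.loc[planted, mut_cols].add(np.sign(fc[planted]), axis=0))
        de2 = call_affected(expr2, classes)
        was = de1.table.loc[planted, key]
        assert de2.table.loc[planted[was], key].all()

    def test_class_with_one_replicate_errors(self):
        expr, classes, _ = _mutant_vs_control(n=2)
        classes = classes.copy()
        classes.iloc[-1] = "lonely"
        with pytest.raises(ValueError, match="fewer than 2"):
            call_affected(expr, classes)

    def test_matches_scipy_anova_and_tukey(self):
        """Vectorized gate agrees with scipy's per-probe routines."""
        rng = np.random.default_rng(5)
        values = rng.normal(10, 1, (30, 12))
        values[:10, 8:] += 2.0
        expr = pd.DataFrame(values, index=[f"p{i}" for i in range(30)],
                            columns=[f"s{j}" for j in range(12)])
        classes = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                            index=expr.columns)
        de = call_affected(expr, classes)
        for i in range(30):
            g = [values[i, :4], values[i, 4:8], values[i, 8:]]
            assert np.isclose(de.table["anova_p"].iloc[i],
                              stats.f_oneway(*g).pvalue, atol=1e-10)
            if de.table["anova_q"].iloc[i] < 0.05:
                ref = stats.tukey_hsd(*g)
                assert np.isclose(de.table["tukey_p[a|b]"].iloc[i],
                                  ref.pvalue[0, 1], atol=2e-3)
                assert np.isclose(de.table["tukey_p[a|c]"].iloc[i],
                                  ref.pvalue[0, 2], atol=2e-3)


def test_tukey_sf_matches_scipy():
    q = np.array([0.5, 1.7, 2.8, 3.6, 5.2, 8.0])
    for k, df in [(3, 9), (4, 15), (7, 28)]:
        ref = stats.studentized_range.sf(q, k, df)
        np.testing.assert_allclose(tukey_sf(q, k, df), ref, atol=5e-4)


class TestOverlap:
    def test_closed_form_example(self):
        """Cells (30, 70, 10, 90) give Yates chi-square ~= 11.28."""
        setA = set(range(100))            # a + b
        setB = set(range(30)) | set(range(100, 110))  # a=30, c=10
        res = overlap_test(setA, setB, 200)
        assert (res.n_AB, res.n_A, res.n_B) == (30, 100, 40)
        assert np.isclose(res.chi2_yates, _yates_closed_form(30, 70, 10, 90),
                          atol=1e-10)
        assert np.isclose(res.chi2_yates, 11.28, atol=0.01)

    def test_yates_not_larger_than_uncorrected(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 60, 4))
            universe = a + b + c + d
            setA = set(range(a + b))
            setB = set(range(a)) | set(range(a + b, a + b + c))
            res = overlap_test(setA, setB, universe)
            uncorrected = stats.chi2_contingency(
                [[a, b], [c, d]], correction=False)[0]
            assert res.chi2_yates <= uncorrected + 1e-12
            assert np.isclose(res.chi2_yates,
                              _yates_closed_form(a, b, c, d), atol=1e-10)

    def test_null_pvalues_roughly_uniform(self):
        """Random independent sets: overlap p-values are not anti-conservative."""
        rng = np.random.default_rng(1)
        universe = 400
        ps = []
        for _ in range(200):
            A = set(rng.choice(universe, 80, replace=False))
            B = set(rng.choice(universe, 80, replace=False))
            ps.append(overlap_test(A, B, universe).p_value)
        assert np.mean(np.array(ps) < 0.05) < 0.08

    def test_errors(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test({1}, {2}, 0)
        with pytest.raises(ValueError, match="exceed"):
            overlap_test(set(range(10)), set(range(10, 20)), 5)


class TestConcordance:
    def test_identity_and_sign_flip(self):
        fx = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        r2, pct = concordance(fx, fx)
        assert r2 == pytest.approx(1.0) and pct == 100.0
        r2, pct = concordance(fx, -fx)
        assert r2 == pytest.approx(1.0) and pct == 0.0

    def test_too_few_shared(self):
        fx = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="3 shared"):
            concordance(fx, fx)


def _de_from_rows(rows):
    """Build a DEResult for contrast (control, x) from (probe, fc, affected)."""
    idx = [r[0] for r in rows]
    table = pd.DataFrame({
        "anova_p": 0.001, "anova_q": 0.001,
        "tukey_p[control|x]": [0.01 if r[2] else 0.9 for r in rows],
        "log2fc[control|x]": [r[1] for r in rows],
        "affected[control|x]": [r[2] for r in rows],
    }, index=pd.Index(idx, name="probe_id"))
    return DEResult(table=table, contrasts=[("control", "x")])


class TestRescue:
    def test_rule_examples(self):
        de_null = _de_from_rows([("p1", 2.0, True), ("p2", 2.0, True),
                                 ("p3", 1.0, True), ("p4", 0.2, False)])
        de_res = _de_from_rows([("p1", 0.1, False),   # back to control: full
                                ("p2", 0.8, True),    # toward but still >1.5x
                                ("p3", 1.4, True)])   # moved away: none
        with pytest.warns(UserWarning, match="absent"):
            de_null2 = _de_from_rows([("p1", 2.0, True), ("p2", 2.0, True),
                                      ("p3", 1.0, True), ("p5", 2.0, True)])
            status = classify_rescue(de_null2, ("control", "x"),
                                     de_res, ("control", "x"))
        assert status.loc["p1", "status"] == "full"
        assert status.loc["p2", "status"] == "partial"
        assert status.loc["p3", "status"] == "none"
        assert status.loc["p5", "status"] == "none"  # missing from rescue
        assert "p4" not in status.index               # not null-affected
        summ = rescue_summary(status)
        assert summ["n_null_affected"] == 4
        assert summ["pct_rescued"] == pytest.approx(50.0)

    def test_synthetic_rescue_mostly_full(self):
        d = SimDesign(n_probes=400, seed=6)
        _, _, truth = generate_control_timecourse(d)
        ctrl, cmeta = generate_mutant_samples(d, truth, 10, genotype="control",
                                              accel_factor=1.0,
                                              offset_scale=0.0, seed_tag=500)
        mut, mmeta = generate_mutant_samples(d, truth, 10, seed_tag=501)
        res, rmeta = generate_mutant_samples(d, truth, 10, genotype="rescue",
                                             accel_factor=1.0,
                                             offset_scale=0.1, seed_tag=502)
        expr = pd.concat([ctrl, mut, res], axis=1)
        meta = pd.concat([cmeta, mmeta, rmeta])
        de = call_affected(expr, sample_classes(meta))
        status = classify_rescue(de, ("control@10", "null@10"),
                                 de, ("control@10", "rescue@10"))
        summ = rescue_summary(status)
        assert summ["n_null_affected"] >= 0.8 * len(truth.mutant_specific_ids)
        assert summ["pct_rescued"] >= 80.0
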