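"""HOMA-IR, excursion AUCs, extreme selection and comparison tests."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xps.metabolic import (
    Excursion,
    PhenotypeRecord,
    anova_one_way,
    anova_two_way,
    auc_trapezoid,
    extreme_select,
    homa_ir,
    homa_ir_table,
    ks_normality,
    load_phenotypes,
    t_test_unpaired,
)

IVGTT_TIMES = (0.0, 1.0, 3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)


class TestHomaIr:
    def test_constant_identity(self):
        assert homa_ir(22.5, 1.0) == 1.0

    def test_zero_insulin(self):
        assert homa_ir(5.0, 0.0) == 0.0

    def test_mets_level_insulin(self):
        # fasting glucose 5.0 mmol/L at the 67 uU/ml insulin level
        assert homa_ir(5.0, 67.0) == pytest.approx(5.0 * 67.0 / 22.5)

    def test_linearity_in_each_argument(self):
        assert homa_ir(2 * 5.0, 67.0) == pytest.approx(2 * homa_ir(5.0, 67.0))
        assert homa_ir(5.0, 3 * 67.0) == pytest.approx(3 * homa_ir(5.0, 67.0))

    def test_nonpositive_glucose_errors(self):
        with pytest.raises(ValueError):
            homa_ir(0.0, 10.0)

    def test_record_derives_index(self):
        rec = PhenotypeRecord("s", "MetS", 40.0, 5.0, 67.0)
        assert rec.homa_ir == pytest.approx(homa_ir(5.0, 67.0))


class TestAuc:
    def test_constant_curve(self):
        exc = Excursion("s", (0.0, 30.0, 60.0), (7.0, 7.0, 7.0))
        assert auc_trapezoid(exc) == pytest.approx(60 * 7.0)

    def test_linear_ramp_is_a_triangle(self):
        exc = Excursion("s", (0.0, 10.0), (0.0, 10.0))
        assert auc_trapezoid(exc) == pytest.approx(50.0)

    def test_matches_fine_grid_refinement(self):
        rng = np.random.default_rng(1)
        values = tuple(float(v) for v in rng.uniform(2, 20, len(IVGTT_TIMES)))
        exc = Excursion("s", IVGTT_TIMES, values)
        grid = np.linspace(0, 60, 60001)
        interp = np.interp(grid, IVGTT_TIMES, values)
        fine = np.trapezoid(interp, grid)
        assert auc_trapezoid(exc) == pytest.approx(fine, abs=1e-9 * fine + 1e-9)

    def test_collinear_midpoint_invariance(self):
        a = Excursion("s", (0.0, 10.0, 20.0), (1.0, 5.0, 3.0))
        b = Excursion("s", (0.0, 5.0, 10.0, 20.0), (1.0, 3.0, 5.0, 3.0))
        assert auc_trapezoid(a) == pytest.approx(auc_trapezoid(b))

    def test_baseline_subtraction_and_floor(self):
        exc = Excursion("s", (0.0, 10.0, 20.0), (5.0, 15.0, 3.0))
        assert auc_trapezoid(exc, baseline_subtract=True) == pytest.approx(
            auc_trapezoid(exc) - 5.0 * 20.0
        )
        floored = auc_trapezoid(exc, baseline_subtract=True, floor_at_zero=True)
        assert floored == pytest.approx(np.trapezoid([0, 10, 0], [0, 10, 20]))

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Excursion("s", (0.0, 10.0, 10.0), (1.0, 2.0, 3.0))

    def test_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            Excursion("s", (1.0, 10.0), (1.0, 2.0))


class TestExtremeSelect:
    def test_gross_outlier_flagged(self):
        values = {"a": 1.0, "b": 2.0, "c": 3.0, "x": 100.0}
        assert extreme_select(values, ["a", "b", "c"]) == ["x"]

    def test_exact_threshold_not_flagged(self):
        # reference {1,2,3}: mean 2, sd 1 -> threshold 5; strict inequality
        values = {"a": 1.0, "b": 2.0, "c": 3.0, "x": 5.0, "y": 5.0001}
        assert extreme_select(values, ["a", "b", "c"]) == ["y"]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        values = {f"s{i}": float(v) for i, v in enumerate(rng.lognormal(3, 0.4, 40))}
        values["out"] = 20 * max(values.values())
        ref = list(values)
        base = extreme_select(values, ref)
        scaled = {k: 7.5 * v for k, v in values.items()}
        assert extreme_select(scaled, ref) == base

    def test_zero_variance_reference(self):
        values = {"a": 2.0, "b": 2.0, "c": 2.0, "x": 2.1, "y": 2.0}
        assert extreme_select(values, ["a", "b", "c"]) == ["x"]

    def test_leave_one_out_keeps_a_reference_member_detectable(self):
        values = {f"s{i}": 10.0 + 0.1 * i for i in range(20)}
        values["s19"] = 500.0
        assert extreme_select(values, list(values)) == ["s19"]

    def test_small_reference_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            extreme_select({"a": 1.0, "b": 2.0}, ["a", "b"])


class TestStudentT:
    def test_identical_distribution_groups(self):
        t, p = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_pooled_statistic(self):
        """{1,2,3} vs {4,5,6}: pooled arithmetic done by hand in-line."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, p = t_test_unpaired(a, b)
        pooled = (2 * 1.0 + 2 * 1.0) / 4  # both sample variances are 1
        t_hand = (2.0 - 5.0) / math.sqrt(pooled * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert t_hand == pytest.approx(-3.6742346141, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df=4), rel=1e-12)

    def test_zero_pooled_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            t_test_unpaired([2.0, 2.0], [3.0, 3.0])


class TestAnova:
    @staticmethod
    def _balanced_2x2():
        # 3 replicates per cell, arbitrary means
        y, fa, fb = [], [], []
        cell_means = {("a1", "b1"): 3.0, ("a1", "b2"): 5.0,
                      ("a2", "b1"): 4.0, ("a2", "b2"): 10.0}
        offsets = [-0.5, 0.0, 0.5]
        for (la, lb), mu in cell_means.items():
            for o in offsets:
                y.append(mu + o)
                fa.append(la)
                fb.append(lb)
        return np.array(y), fa, fb, cell_means, offsets

    def test_balanced_2x2_matches_hand_decomposition(self):
        y, fa, fb, cell_means, offsets = self._balanced_2x2()
        res = anova_two_way(y, fa, fb)
        r = len(offsets)
        grand = np.mean(list(cell_means.values()))
        a_means = {"a1": 4.0, "a2": 7.0}
        b_means = {"b1": 3.5, "b2": 7.5}
        ss_a = 2 * r * sum((m - grand) ** 2 for m in a_means.values())
        ss_b = 2 * r * sum((m - grand) ** 2 for m in b_means.values())
        ss_ab = r * sum(
            (mu - a_means[la] - b_means[lb] + grand) ** 2
            for (la, lb), mu in cell_means.items()
        )
        ss_err = 4 * sum(o ** 2 for o in offsets)
        ms_err = ss_err / (12 - 4)
        assert res.f_a == pytest.approx(ss_a / 1 / ms_err, abs=1e-9)
        assert res.f_b == pytest.approx(ss_b / 1 / ms_err, abs=1e-9)
        assert res.f_interaction == pytest.approx(ss_ab / 1 / ms_err, abs=1e-9)

    def test_pure_additive_design_has_no_interaction(self):
        y, fa, fb = [], [], []
        for la, a_eff in (("a1", 0.0), ("a2", 2.0)):
            for lb, b_eff in (("b1", 0.0), ("b2", 5.0)):
                for o in (-0.3, 0.1, 0.2):
                    y.append(1.0 + a_eff + b_eff + o)
                    fa.append(la)
                    fb.append(lb)
        res = anova_two_way(y, fa, fb)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-10)

    def test_two_level_one_factor_f_is_t_squared(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 14)
        b = rng.normal(0.5, 1, 17)
        t, p_t = t_test_unpaired(a, b)
        f, p_f = anova_one_way(np.concatenate([a, b]),
                               ["a"] * len(a) + ["b"] * len(b))
        assert f == pytest.approx(t ** 2, abs=1e-9)
        assert p_f == pytest.approx(p_t, abs=1e-12)

    def test_single_level_factor_errors(self):
        with pytest.raises(ValueError, match="two levels"):
            anova_two_way([1.0, 2.0], ["a", "a"], ["b", "c"])

    def test_saturated_design_errors(self):
        with pytest.raises(ValueError, match="replication"):
            anova_two_way([1.0, 2.0, 3.0, 4.0],
                          ["a", "a", "b", "b"], ["c", "d", "c", "d"])


class TestKsNormality:
    def test_d_statistic_matches_direct_scan(self):
        rng = np.random.default_rng(12)
        x = rng.normal(3, 2, 60)
        d, _ = ks_normality(x)
        xs = np.sort(x)
        cdf = stats.norm.cdf(xs, np.mean(x), np.std(x, ddof=1))
        n = len(x)
        d_scan = max(
            max(abs((i + 1) / n - c), abs(i / n - c)) for i, c in enumerate(cdf)
        )
        assert d == pytest.approx(d_scan, abs=1e-12)

    def test_normal_samples_usually_pass(self):
        passes = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(0, 1, 500)
            _, p = ks_normality(x)
            passes += p > 0.05
        assert passes >= 18

    def test_two_point_distribution_fails(self):
        x = np.array([0.0, 1.0] * 30)
        _, p = ks_normality(x)
        assert p < 1e-4

    def test_degenerate_samples(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])


class TestPhenotypeTable:
    def test_mgdl_units_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"subject": ["s"], "group": ["control"], "timepoint_months": [0.0],
             "analyte": ["fasting_glucose"], "value": [90.0], "unit": ["mg/dL"]}
        )
        path = tmp_path / "p.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="convert"):
            load_phenotypes(path)

    def test_homa_table_from_generated_phenotypes(self, study, tmp_path):
        path = tmp_path / "pheno.tsv"
        study.phenotypes.to_csv(path, sep="\t", index=False)
        df = load_phenotypes(path)
        homa = homa_ir_table(df)
        assert {"subject", "group", "timepoint_months", "homa_ir"} <= set(homa.columns)
        merged = homa.groupby("group")["homa_ir"].median()
        assert merged["case"] > merged["MetS"] > merged["control"]
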