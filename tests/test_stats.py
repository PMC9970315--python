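"""ΔΔCt quantification, percent conversions, pooled t-tests, cohort
summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from regpath.simulate import QpcrSimConfig, default_cohort_config, \
    gen_cohort, gen_qpcr
from regpath.stats import (
    cohort_summary,
    delta_delta_ct,
    fold_from_suppression,
    normalize_measurement,
    percent_change,
    percent_suppression,
    pooled_t_test,
    t_test_from_summary,
)


def qpcr_table(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


class TestDeltaDeltaCt:
    def test_identical_groups_give_fold_one(self):
        table = qpcr_table([
            ("t1", "OM", "g", 25.0), ("t1", "OM", "ref", 20.0),
            ("c1", "ctrl", "g", 25.0), ("c1", "ctrl", "ref", 20.0),
        ])
        fc = delta_delta_ct(table, "g", "ref", "OM", "ctrl")
        assert fc.delta_delta_ct == 0.0
        assert fc.fold_change == 1.0

    def test_two_cycle_shift_gives_quarter_fold(self):
        table = qpcr_table([
            ("t1", "OM", "g", 26.0), ("t1", "OM", "ref", 20.0),
            ("c1", "ctrl", "g", 24.0), ("c1", "ctrl", "ref", 20.0),
        ])
        fc = delta_delta_ct(table, "g", "ref", "OM", "ctrl")
        assert fc.delta_delta_ct == 2.0
        assert fc.fold_change == 0.25
        assert fc.percent_change == -75.0
        assert fc.percent_suppression == 75.0

    def test_noiseless_generator_round_trip(self):
        cfg = QpcrSimConfig(
            genes=["g", "GAPDH"], fold_changes={"OM": {"g": 0.42}},
            ct_noise_sd=0.0, n_replicates=4, seed=0,
        )
        fc = delta_delta_ct(gen_qpcr(cfg), "g", "GAPDH", "OM", "control")
        assert fc.fold_change == pytest.approx(0.42, abs=1e-12)

    def test_replicate_cts_averaged_within_sample(self):
        table = qpcr_table([
            ("t1", "OM", "g", 26.0), ("t1", "OM", "g", 28.0),
            ("t1", "OM", "ref", 20.0),
            ("c1", "ctrl", "g", 24.0), ("c1", "ctrl", "ref", 20.0),
        ])
        fc = delta_delta_ct(table, "g", "ref", "OM", "ctrl")
        assert fc.delta_ct_treated == 7.0

    def test_swapping_contrast_inverts_fold(self):
        rng = np.random.default_rng(0)
        rows = []
        for grp in ("a", "b"):
            for i in range(4):
                rows += [
                    (f"{grp}{i}", grp, "g", 24 + rng.normal()),
                    (f"{grp}{i}", grp, "ref", 20 + rng.normal()),
                ]
        table = qpcr_table(rows)
        ab = delta_delta_ct(table, "g", "ref", "a", "b")
        ba = delta_delta_ct(table, "g", "ref", "b", "a")
        assert ab.fold_change * ba.fold_change == pytest.approx(1.0)

    def test_sample_missing_reference_dropped_with_warning(self):
        table = qpcr_table([
            ("t1", "OM", "g", 26.0), ("t1", "OM", "ref", 20.0),
            ("t2", "OM", "g", 30.0),  # no reference Ct → dropped
            ("c1", "ctrl", "g", 24.0), ("c1", "ctrl", "ref", 20.0),
        ])
        with pytest.warns(UserWarning, match="dropped 1 sample"):
            fc = delta_delta_ct(table, "g", "ref", "OM", "ctrl")
        assert fc.n_treated == 1
        assert fc.delta_delta_ct == 2.0

    def test_empty_group_after_drops_rejected(self):
        table = qpcr_table([
            ("t1", "OM", "g", 26.0),
            ("c1", "ctrl", "g", 24.0), ("c1", "ctrl", "ref", 20.0),
        ])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no sample"):
                delta_delta_ct(table, "g", "ref", "OM", "ctrl")

    def test_unknown_group_rejected(self):
        table = qpcr_table([("t1", "OM", "g", 26.0)])
        with pytest.raises(ValueError, match="'nope'"):
            delta_delta_ct(table, "g", "g", "nope", "OM")


class TestPercentConversions:
    @pytest.mark.parametrize("fold,percent", [
        (1.0, 0.0), (0.42, 58.0), (0.5, 50.0), (2.0, -100.0),
    ])
    def test_percent_suppression(self, fold, percent):
        assert percent_suppression(fold) == pytest.approx(percent)

    def test_inverse_conversion(self):
        for s in (58.0, 32.0, 42.0, -71.0):
            assert percent_suppression(fold_from_suppression(s)) == \
                pytest.approx(s)

    def test_percent_change_convention(self):
        assert percent_change(1.71) == pytest.approx(71.0)
        assert percent_change(1.0) == 0.0

    def test_nonpositive_fold_rejected(self):
        for fn in (percent_suppression, percent_change):
            with pytest.raises(ValueError):
                fn(0.0)


class TestPooledTTest:
    def test_identical_samples(self):
        res = pooled_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_constant_shift_closed_form(self):
        """x=(1,2,3) vs x+2: t = -2 / (1·sqrt(2/3)) ≈ -2.449."""
        res = pooled_t_test([1, 2, 3], [3, 4, 5])
        assert res.t == pytest.approx(-2.0 / math.sqrt(2.0 / 3.0))
        assert res.df == 4

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 5)
        a, b = pooled_t_test(x, y), pooled_t_test(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            pooled_t_test([1.0, 1.0], [2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            pooled_t_test([1.0], [1.0, 2.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_scipy_to_1e10(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, int(rng.integers(2, 30)))
        y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                       int(rng.integers(2, 30)))
        res = pooled_t_test(x, y)
        t_ref, p_ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_summary_form_equals_raw_form(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 2, 6)
        raw = pooled_t_test(x, y)
        summ = t_test_from_summary(
            x.mean(), x.std(ddof=1), x.size,
            y.mean(), y.std(ddof=1), y.size,
        )
        assert summ.t == pytest.approx(raw.t)
        assert summ.p == pytest.approx(raw.p)
        assert summ.df == raw.df


class TestNormalize:
    def test_simple_ratio(self):
        assert normalize_measurement(10.0, 2.0).normalized == 5.0
        assert normalize_measurement(0.0, 2.0).normalized == 0.0

    def test_scale_invariance(self):
        a = normalize_measurement(10.0, 2.0)
        b = normalize_measurement(20.0, 4.0)
        assert a.normalized == b.normalized

    def test_units_recorded(self):
        m = normalize_measurement(10.0, 2.0, "ug_calcium", "mg_protein")
        assert m.units == "ug_calcium/mg_protein"

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            normalize_measurement(1.0, 0.0)


class TestCohortSummary:
    def test_sex_percent_one_decimal(self):
        cohort = pd.DataFrame({
            "subject": [f"s{i}" for i in range(35)],
            "group": ["a"] * 24 + ["b"] * 11,
            "sex": ["M"] * 13 + ["F"] * 22,
            "age": np.linspace(70, 80, 35),
            "x": np.ones(35),
        })
        s = cohort_summary(cohort, sex_category="M")
        assert s.total_n == 35
        assert s.sex_count == 13
        assert s.sex_percent == 37.1

    def test_identical_subjects_have_sd_zero(self):
        cohort = pd.DataFrame({
            "group": ["a"] * 4, "sex": ["F"] * 4,
            "age": [70.0] * 4, "x": [2.0] * 4,
        })
        s = cohort_summary(cohort)
        assert s.groups["a"].biomarkers["x"] == (2.0, 0.0)

    def test_generator_group_sizes(self):
        s = cohort_summary(gen_cohort(default_cohort_config(seed=2)))
        assert {k: v.n for k, v in s.groups.items()} == \
            {"non-AAC": 24, "severe-AAC": 11}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(pd.DataFrame())

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            cohort_summary(pd.DataFrame({"group": ["a"], "age": [1.0]}))
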