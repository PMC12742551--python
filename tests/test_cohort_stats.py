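"""Cohort aggregation, the statistical test battery, and time accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wpqa
from wpqa.cohort import (ALPHA, PerStepTimes, deviation_in_mgy,
                         records_to_frame, rounded_pass_rate)


def rec(mean=0.0, mn=-2.0, mx=2.0, passed=True, human_error=False,
        time_s=200.0, n_active=21, **kw):
    base = dict(field_id="F", room="Hx", ion="p", tps="Syngo", rashi=False,
                indication="head", year=2020, pos_a=100.0, pos_b=0.0,
                pos_c=0.0, volume_cm3=100.0, mean_dev=mean, sd_dev=1.0,
                min_dev=mn, max_dev=mx, n_active=n_active, time_s=time_s,
                passed=passed, human_error=human_error)
    base.update(kw)
    return wpqa.FieldRecord(**base)


class TestExcludeAndAggregate:
    def test_exclude_flagged(self):
        records = [rec() for _ in range(8)] + \
            [rec(human_error=True) for _ in range(2)]
        kept, dropped = wpqa.exclude_flagged(records)
        assert len(kept) == 8 and dropped == 2
        kept2, dropped2 = wpqa.exclude_flagged(records[:8])
        assert len(kept2) == 8 and dropped2 == 0
        empty, d0 = wpqa.exclude_flagged([])
        assert len(empty) == 0 and d0 == 0

    def test_hand_made_aggregate(self):
        records = [rec(mean=-1.0, mn=-3.0, mx=2.0, passed=True),
                   rec(mean=0.0, mn=-2.0, mx=4.0, passed=True),
                   rec(mean=1.0, mn=-8.0, mx=9.0, passed=False)]
        out = wpqa.aggregate(records)
        row = out.loc["all"]
        assert row["mean"] == pytest.approx(0.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["min"] == pytest.approx(-8.0)
        assert row["max"] == pytest.approx(9.0)
        assert row["pass_rate_pct"] == pytest.approx(100 * 2 / 3)

    def test_single_record_group(self):
        out = wpqa.aggregate([rec(mean=0.7)])
        assert out.loc["all", "mean"] == pytest.approx(0.7)
        assert out.loc["all", "sd"] == 0.0
        assert bool(out.loc["all", "single_record"])

    def test_partition_conserves_counts(self):
        rng = np.random.default_rng(2)
        records = [rec(ion=rng.choice(["p", "C", "He"]),
                       passed=bool(rng.random() < 0.9)) for _ in range(200)]
        total = wpqa.aggregate(records)
        per_ion = wpqa.aggregate(records, by="ion")
        assert per_ion["n"].sum() == total.loc["all", "n"] == 200
        assert ((per_ion["passed"] + per_ion["failed"]) == per_ion["n"]).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        records = [rec(mean=float(rng.normal(0, 0.5)), mn=-5.0, mx=5.0,
                       ion=str(rng.choice(["p", "C"]))) for _ in range(50)]
        a = wpqa.aggregate(records, by="ion")
        b = wpqa.aggregate(list(reversed(records)), by="ion")
        pd.testing.assert_frame_equal(a, b)


class TestShiftTests:
    def test_symmetric_sample_not_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 5000)
        assert not wpqa.test_mean_shift(x).significant

    def test_large_shifted_sample_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(-0.5, 0.9, 23014)
        res = wpqa.test_mean_shift(x)
        assert res.significant and res.p_value < 1e-100

    def test_five_value_t_against_textbook_critical_value(self):
        # mean 2, sample sd sqrt(0.625), n 5 -> t = 4*sqrt(2) = 5.657,
        # beyond the two-sided 0.01 critical value at 4 dof (4.604) but
        # short of the 0.001 row (8.610)
        x = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        res = wpqa.test_mean_shift(x)
        assert res.statistic == pytest.approx(4.0 * np.sqrt(2.0), rel=1e-9)
        assert 0.001 < res.p_value < 0.01

    def test_wilcoxon_shift_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(-0.5, 0.5, 500)
        assert wpqa.test_median_shift(x).significant

    def test_wilcoxon_identical_values_rejected(self):
        with pytest.raises(ValueError):
            wpqa.test_median_shift(np.ones(10))


class TestGroupComparisons:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 200)
        assert not wpqa.compare_groups(x[:100], x[100:]).significant

    def test_three_sd_shift_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 100)
        b = rng.normal(3, 1, 100)
        res = wpqa.compare_groups(a, b)
        assert res.significant

    def test_levene_gate_picks_welch_for_unequal_variances(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 400)
        b = rng.normal(0, 5, 400)
        res = wpqa.compare_groups(a, b)
        assert res.test == "Welch t"

    def test_anova_tukey_flags_only_shifted_group(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 100), "b": rng.normal(0, 1, 100),
                  "c": rng.normal(2, 1, 100)}
        res, tukey = wpqa.compare_multi(groups)
        assert res.significant and tukey is not None
        flagged = {
            tuple(sorted((row["group1"], row["group2"])))
            for _, row in tukey.iterrows() if row["reject"]}
        assert flagged == {("a", "c"), ("b", "c")}

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            wpqa.compare_multi({"a": np.ones(5), "b": np.zeros(5)})


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert wpqa.correlate(x, x).statistic == pytest.approx(1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(9)
        r = wpqa.correlate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r.statistic) < 0.1

    def test_negative_slope_negative_r(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        y = -x + rng.normal(0, 0.5, 200)
        assert wpqa.correlate(y, x).statistic < 0

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError):
            wpqa.correlate(np.arange(5.0), np.ones(5))


class TestTimeAccounting:
    def test_zero_records(self):
        out = wpqa.time_accounting([], n_verifications=0, n_sessions=0)
        assert out["total_h"] == 0.0

    def test_two_verifications_one_session_overhead(self):
        out = wpqa.time_accounting([120.0, 180.0], PerStepTimes(),
                                   n_sessions=1)
        # 2 x (15 + 10) + 1 x (30 + 5) = 85 min
        assert out["overhead_h"] == pytest.approx(85.0 / 60.0)
        assert out["beam_time_h"] == pytest.approx(300.0 / 3600.0)

    def test_component_totals_sum(self):
        out = wpqa.time_accounting([], n_verifications=0, n_sessions=0)
        assert out["beam_time_h"] + out["overhead_h"] == out["total_h"]


class TestHelpers:
    def test_deviation_in_mgy(self):
        assert deviation_in_mgy(0.3, 2.0) == pytest.approx(6.0)

    def test_rounded_pass_rate(self):
        assert rounded_pass_rate(20909, 23014) == 91
        with pytest.raises(ValueError):
            rounded_pass_rate(1, 0)


class TestThresholdSensitivity:
    def test_baseline_threshold_reproduces_direct_result(self, noisy_cohort):
        records, tables = noisy_cohort
        out = wpqa.threshold_sensitivity(tables, [0.05])
        direct = 100.0 * sum(r.passed for r in records) / len(records)
        assert out.loc[0, "pass_rate_pct"] == pytest.approx(direct)

    def test_huge_threshold_activates_everything(self, noisy_cohort):
        _, tables = noisy_cohort
        out = wpqa.threshold_sensitivity(tables, [1e9])
        finite = [np.isfinite(t.gradients).all() for t in tables]
        expected = [24 if f else int(np.isfinite(t.gradients).sum())
                    for f, t in zip(finite, tables)]
        assert list(out.loc[0, "n_active"]) == expected

    def test_constructed_cohort_gains_from_stricter_threshold(self):
        # deviations concentrated in the highest-gradient chambers: excluding
        # them rescues the field
        planned = np.full(24, 2.0)
        measured = planned.copy()
        gradients = np.zeros(24)
        measured[:3] += 0.2          # +10% of D_max, beyond +7%
        gradients[:3] = 90.0         # 4.5% of D_max per mm
        recs = [wpqa.VerificationRecord(planned=planned, measured=measured,
                                        gradients=gradients, d_max=2.0)]
        out = wpqa.threshold_sensitivity(recs, [0.05, 0.04])
        assert out.loc[0, "threshold_fraction"] == 0.05
        assert out.loc[0, "pass_rate_pct"] == 0.0
        assert out.loc[1, "pass_rate_pct"] == 100.0
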