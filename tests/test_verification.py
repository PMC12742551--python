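"""Gradient estimation, chamber activation, deviation scoring, pass/fail."""

import numpy as np
import pytest

import wpqa
from wpqa.chambers import POINT_CHAMBER
from wpqa.verify import (DeviationSummary, NoEvaluableChambersError,
                         RepeatPolicyConfig, _gradient, repeat_policy)
from conftest import uniform_grid


def make_record(planned, measured, gradients=None, d_max=2.0):
    planned = np.asarray(planned, dtype=float)
    full_p = np.full(24, planned[-1])
    full_p[:len(planned)] = planned
    full_m = np.full(24, np.asarray(measured, dtype=float)[-1])
    full_m[:len(measured)] = measured
    g = np.zeros(24) if gradients is None else np.asarray(gradients, float)
    return wpqa.VerificationRecord(planned=full_p, measured=full_m,
                                   gradients=g, d_max=d_max)


class TestGradient:
    def test_uniform_grid_has_zero_gradient(self):
        grid = uniform_grid(2.0, n=11)
        assert wpqa.estimate_gradient(grid, (11.0, 0.0, 0.0)) == 0.0

    def test_linear_ramp_gradient(self):
        # dose rises 1 mGy per mm along A, 2 mm spacing:
        # (d(x+2) - d(x-2)) / 4 = 1.0 mGy/mm
        n, spacing = 21, 2.0
        a = (np.arange(n) + 0.5) * spacing
        values = np.tile(0.001 * a[:, None, None], (1, n, n))
        grid = wpqa.DoseGrid(origin=(0.0, -21.0, -21.0), spacing=spacing,
                             values=values)
        g = wpqa.estimate_gradient(grid, (21.0, 0.0, 0.0))
        assert g == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_smooth_grids(self):
        # independent oracle: explicit indexing of the six neighbors
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, spacing = 9, rng.choice([1.0, 2.0])
            base = rng.random((n, n, n))
            # smooth by separable averaging
            for ax in range(3):
                base = (np.roll(base, 1, ax) + base + np.roll(base, -1, ax)) / 3
            grid = wpqa.DoseGrid(origin=(0.0, 0.0, 0.0), spacing=spacing,
                                 values=base)
            i, j, k = rng.integers(1, n - 1, size=3)
            pos = (np.array([i, j, k]) + rng.random(3)) * spacing
            expected = 1000.0 * np.sqrt(
                ((base[i + 1, j, k] - base[i - 1, j, k]) / (2 * spacing)) ** 2
                + ((base[i, j + 1, k] - base[i, j - 1, k]) / (2 * spacing)) ** 2
                + ((base[i, j, k + 1] - base[i, j, k - 1]) / (2 * spacing)) ** 2)
            assert wpqa.estimate_gradient(grid, pos) == \
                pytest.approx(expected, abs=1e-9)

    def test_boundary_voxel_raises(self):
        grid = uniform_grid(2.0, n=11)
        with pytest.raises(ValueError, match="neighbor"):
            wpqa.estimate_gradient(grid, (1.0, 0.0, 0.0))


class TestActivation:
    def test_gradient_above_threshold_deactivates(self):
        d_max = 2.0  # Gy -> 2000 mGy; 5% threshold = 100 mGy/mm
        rec = make_record([2.0] * 24, [2.0] * 24,
                          gradients=[0.06 * 2000.0] + [0.0] * 23, d_max=d_max)
        active = wpqa.select_active_chambers(rec, wpqa.ToleranceConfig())
        assert not active[0] and active[1:].all()

    def test_boundary_equality_keeps_active(self):
        rec = make_record([2.0] * 24, [2.0] * 24,
                          gradients=[0.05 * 2000.0] + [0.0] * 23)
        active = wpqa.select_active_chambers(rec, wpqa.ToleranceConfig())
        assert active.all()

    def test_threshold_dependence(self):
        rec = make_record([2.0] * 24, [2.0] * 24,
                          gradients=[0.045 * 2000.0] + [0.0] * 23)
        at5 = wpqa.select_active_chambers(
            rec, wpqa.ToleranceConfig(gradient_threshold_fraction=0.05))
        assert at5[0]
        at4 = wpqa.select_active_chambers(
            rec, wpqa.ToleranceConfig(gradient_threshold_fraction=0.04))
        assert not at4[0]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        rec = make_record([2.0] * 24, [2.0] * 24,
                          gradients=rng.uniform(0, 200, 24))
        prev = np.ones(24, dtype=bool)
        for frac in (0.08, 0.06, 0.05, 0.04, 0.02, 0.01):
            act = wpqa.select_active_chambers(
                rec, wpqa.ToleranceConfig(gradient_threshold_fraction=frac))
            assert np.all(act <= prev)   # set inclusion
            prev = act


class TestDeviationSummary:
    def test_hand_arithmetic_example(self):
        rec = make_record([2.00, 2.00], [2.02, 1.94], d_max=2.0)
        rec.active = np.array([True, True] + [False] * 22)
        s = wpqa.compute_deviation_summary(rec)
        assert s.deviations[0] == pytest.approx(1.0)
        assert s.deviations[1] == pytest.approx(-3.0)
        assert s.mean == pytest.approx(-1.0)
        assert s.min == pytest.approx(-3.0)
        assert s.max == pytest.approx(1.0)
        assert s.n_active == 2

    def test_identity_measurement_scores_zero(self):
        rec = make_record([2.0] * 24, [2.0] * 24)
        wpqa.select_active_chambers(rec, wpqa.ToleranceConfig())
        s = wpqa.compute_deviation_summary(rec)
        assert s.mean == s.min == s.max == 0.0
        assert wpqa.classify(s).passed

    def test_single_active_chamber(self):
        rec = make_record([2.0] * 24, [2.1] * 24, d_max=2.0)
        rec.active = np.array([True] + [False] * 23)
        s = wpqa.compute_deviation_summary(rec)
        assert s.mean == s.min == s.max == pytest.approx(5.0)
        assert s.sd == 0.0

    def test_no_active_chambers_raises(self):
        rec = make_record([2.0] * 24, [2.0] * 24)
        rec.active = np.zeros(24, dtype=bool)
        with pytest.raises(NoEvaluableChambersError):
            wpqa.compute_deviation_summary(rec)

    def test_normalization_invariance(self):
        rng = np.random.default_rng(5)
        planned = rng.uniform(1.0, 2.0, 24)
        measured = planned * rng.uniform(0.95, 1.05, 24)
        for scale in (1.0, 3.7):
            rec = make_record(planned * scale, measured * scale, d_max=2.0 * scale)
            wpqa.select_active_chambers(rec, wpqa.ToleranceConfig())
            s = wpqa.compute_deviation_summary(rec)
            if scale == 1.0:
                ref = s
            else:
                np.testing.assert_allclose(s.deviations, ref.deviations,
                                           rtol=1e-12)
                assert wpqa.classify(s).passed == wpqa.classify(ref).passed


def summary_from(mean, mn, mx, n_active=20):
    devs = np.zeros(24)
    devs[0], devs[1], devs[2] = mn, mx, mean
    active = np.zeros(24, dtype=bool)
    active[:n_active] = True
    return DeviationSummary(deviations=devs, active=active, mean=mean,
                            sd=0.0, min=mn, max=mx, n_active=n_active)


class TestClassify:
    @pytest.mark.parametrize("mean,mn,mx,passed,violated", [
        (-4.9, -6.9, 6.9, True, ()),
        (-5.1, 0.0, 0.0, False, ("mean",)),
        (0.0, -7.5, 2.0, False, ("minimum",)),
        (0.0, -2.0, 7.2, False, ("maximum",)),
        (5.0, -7.0, 7.0, True, ()),           # boundaries inclusive
        (-6.0, -8.0, 9.0, False, ("mean", "minimum", "maximum")),
    ])
    def test_tolerance_rules(self, mean, mn, mx, passed, violated):
        result = wpqa.classify(summary_from(mean, mn, mx))
        assert result.passed is passed
        assert result.violated_criteria == violated

    def test_chamber_classes(self):
        s = summary_from(0.0, -6.0, 8.0)
        result = wpqa.classify(s)
        assert result.chamber_classes[0] == "active_5_to_7"
        assert result.chamber_classes[1] == "active_beyond_7"
        assert result.chamber_classes[2] == "active_within_5"
        assert result.chamber_classes[-1] == "deactivated"


class TestVerifyField:
    def test_zero_error_pipeline_passes(self, sobp_grid):
        layout = wpqa.default_stack_layout()
        session = wpqa.MeasurementSession(placement=(105.0, 0.0, 0.0))
        measured = wpqa.simulate_measurement(sobp_grid, layout, session,
                                             POINT_CHAMBER)
        result, record = wpqa.verify_field(sobp_grid, layout, session,
                                           measured, spec=POINT_CHAMBER)
        assert result.passed
        assert abs(result.summary.mean) < 0.2

    def test_six_percent_bias_fails_on_mean(self, sobp_grid):
        layout = wpqa.default_stack_layout()
        em = wpqa.ErrorModel(calibration_bias=0.06)
        session = wpqa.MeasurementSession(placement=(105.0, 0.0, 0.0),
                                          error_model=em)
        measured = wpqa.simulate_measurement(sobp_grid, layout, session,
                                             POINT_CHAMBER)
        result, _ = wpqa.verify_field(sobp_grid, layout, session, measured,
                                      spec=POINT_CHAMBER)
        assert not result.passed
        assert "mean" in result.violated_criteria

    def test_all_chambers_in_steep_gradient_is_degenerate(self, sobp_grid):
        layout = wpqa.default_stack_layout()
        session = wpqa.MeasurementSession(placement=(105.0, 0.0, 0.0))
        measured = wpqa.simulate_measurement(sobp_grid, layout, session,
                                             POINT_CHAMBER)
        tol = wpqa.ToleranceConfig(gradient_threshold_fraction=1e-9)
        with pytest.raises(NoEvaluableChambersError):
            wpqa.verify_field(sobp_grid, layout, session, measured, tol,
                              POINT_CHAMBER)


class TestRepeatPolicy:
    def _result(self, passed, beyond=0):
        classes = ["active_beyond_7"] * beyond \
            + ["active_within_5"] * (24 - beyond)
        s = summary_from(0.0, -1.0, 1.0)
        return wpqa.VerificationResult(
            summary=s, passed=passed,
            violated_criteria=() if passed else ("maximum",),
            chamber_classes=tuple(classes))

    def test_pass_accepts(self):
        assert repeat_policy(self._result(True)) == "accept"

    def test_first_failure_repeats(self):
        assert repeat_policy(self._result(False)) == "repeat_measurement"

    def test_persistent_widespread_failure_adapts_plan(self):
        res = self._result(False, beyond=5)
        rec = make_record([2.0] * 24, [2.0] * 24, gradients=np.zeros(24))
        action = repeat_policy(res, history=(self._result(False),),
                               record=rec)
        assert action == "adapt_plan"

    def test_few_high_gradient_chambers_justified(self):
        res = self._result(False, beyond=2)
        g = np.zeros(24)
        g[:2] = 90.0   # the failing chambers sit in the steepest gradients
        rec = make_record([2.0] * 24, [2.0] * 24, gradients=g)
        action = repeat_policy(res, history=(self._result(False),),
                               record=rec,
                               policy=RepeatPolicyConfig())
        assert action == "accept_with_justification"
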