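import numpy as np
import pytest

from vo2kinetics import (
    KineticParams,
    ModelFamily,
    evaluate,
    exercise_component,
    gradient,
    mean_response_time,
    recovery_component,
)
from vo2kinetics.models import PARAM_NAMES

from conftest import canonical_params, finite_difference

FAMILIES = list(ModelFamily)


class TestExerciseComponent:
    def test_zero_at_onset_and_before(self):
        p = canonical_params()
        assert exercise_component(p.lam, p) == 0.0
        assert exercise_component(0.0, p) == 0.0

    def test_hand_value_one_tau_after_onset(self):
        # 700·(1 − e⁻¹) at t = lam + tau1
        p = canonical_params()
        np.testing.assert_allclose(exercise_component(90.0, p), 442.48, atol=0.005)

    def test_asymptote(self):
        p = canonical_params()
        t = p.lam + 50.0 * p.tau1
        np.testing.assert_allclose(exercise_component(t, p), 700.0, atol=1e-6)

    def test_monotone_nondecreasing(self):
        p = canonical_params()
        t = np.linspace(0.0, 2000.0, 400)
        assert np.all(np.diff(exercise_component(t, p)) >= 0)

    def test_nonfinite_time_rejected(self):
        p = canonical_params()
        with pytest.raises(ValueError):
            exercise_component(np.nan, p)


class TestRecoveryComponent:
    @pytest.mark.parametrize(
        "family,fraction",
        [
            (ModelFamily.LOG_LOGISTIC, 0.5),
            (ModelFamily.WEIBULL_1, np.exp(-1.0)),
            (ModelFamily.WEIBULL_2, 1.0 - np.exp(-1.0)),
        ],
    )
    def test_fraction_at_one_t_half(self, family, fraction):
        p = canonical_params(family)
        t = p.recovery_onset + p.t_half
        expected = (p.vo2_rec - p.vo2_ss) * fraction
        np.testing.assert_allclose(recovery_component(t, p, family), expected, rtol=1e-12)

    @pytest.mark.parametrize("tau2", [-0.5, -2.0, -7.0])
    def test_log_logistic_half_decrease_for_any_steepness(self, tau2):
        p = canonical_params(tau2=tau2)
        t = p.recovery_onset + p.t_half
        np.testing.assert_allclose(
            recovery_component(t, p, "log_logistic"),
            0.5 * (p.vo2_rec - p.vo2_ss),
            rtol=1e-12,
        )

    @pytest.mark.parametrize("family", FAMILIES)
    def test_sign_convention_limits(self, family):
        # canonical tau2 sign: → 0 just after onset, → full span far out
        p = canonical_params(family)
        t0 = p.recovery_onset
        span = p.vo2_rec - p.vo2_ss
        near = recovery_component(t0 + 1e-6 * p.t_half, p, family)
        far = recovery_component(t0 + 1e3 * p.t_half, p, family)
        assert abs(near) < 1e-6 * abs(span)
        np.testing.assert_allclose(far, span, rtol=5e-3)

    def test_zero_before_onset(self):
        p = canonical_params()
        assert recovery_component(p.recovery_onset, p, "log_logistic") == 0.0

    @pytest.mark.parametrize("family", FAMILIES)
    def test_strictly_decreasing_during_recovery(self, family):
        # grid kept within [T1/2/4, 3×T1/2]: outside it the Weibull tails are
        # double-exponentially flat and consecutive floats tie
        p = canonical_params(family)
        t = p.recovery_onset + np.linspace(30.0, 400.0, 150)
        vals = recovery_component(t, p, family)
        assert np.all(np.diff(vals) < 0)

    def test_family_ordering_at_t_half(self):
        # Weibull 1 has achieved less of the decrease at t0+T1/2 than the
        # log-logistic, Weibull 2 more — hence lower/higher fitted T1/2.
        for offset in (0.5, 1.0, 2.0, 5.0):
            vals = {}
            for family in FAMILIES:
                p = canonical_params(family)
                t = p.recovery_onset + offset * p.t_half
                vals[family] = abs(recovery_component(t, p, family))
            if offset == 1.0:
                assert (
                    vals[ModelFamily.WEIBULL_1]
                    < vals[ModelFamily.LOG_LOGISTIC]
                    < vals[ModelFamily.WEIBULL_2]
                )

    def test_invalid_t_half_rejected(self):
        p = canonical_params(t_half=-1.0)
        with pytest.raises(ValueError):
            recovery_component(700.0, p, "log_logistic")


class TestEvaluate:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_rest_plateau_recovery_phases(self, family):
        p = canonical_params(family)
        np.testing.assert_array_equal(evaluate(0.0, p, family), p.vo2_rest)
        plateau_t = p.lam + 12.0 * p.tau1
        assert abs(evaluate(plateau_t, p, family) - p.vo2_ss) < 1e-3 * (p.vo2_ss - p.vo2_rest)
        far = p.recovery_onset + 1e4 * p.t_half
        np.testing.assert_allclose(evaluate(far, p, family), p.vo2_rec, rtol=1e-3)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_continuity_at_phase_boundaries(self, family):
        p = canonical_params(family)
        for t_star in (p.lam, p.recovery_onset):
            left = evaluate(t_star - 1e-9, p, family)
            right = evaluate(t_star + 1e-9, p, family)
            np.testing.assert_allclose(left, right, rtol=0, atol=1e-5)

    def test_vectorizes(self):
        p = canonical_params()
        t = np.array([0.0, 100.0, 400.0, 600.0])
        assert evaluate(t, p, "log_logistic").shape == (4,)


class TestGradient:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_finite_differences(self, family):
        p = canonical_params(family)
        t = np.array([5.0, 61.0, 95.0, 200.0, 419.0, 421.0, 480.0, 540.0, 700.0, 1000.0])
        g = gradient(t, p, family)
        fd = finite_difference(t, p, family)
        scale = np.maximum(np.abs(fd), 1.0)
        assert np.max(np.abs(g - fd) / scale) < 1e-6

    def test_trivial_entries(self):
        p = canonical_params()
        g = gradient([10.0, 30.0], p, "log_logistic")
        np.testing.assert_array_equal(g[:, PARAM_NAMES.index("vo2_rest")], 1.0)
        g2 = gradient([100.0, 400.0], p, "log_logistic")  # before recovery onset
        np.testing.assert_array_equal(g2[:, PARAM_NAMES.index("t_half")], 0.0)


class TestMeanResponseTime:
    @pytest.mark.parametrize("tau1", [30.0, 45.5])
    def test_equals_tau1(self, tau1):
        assert mean_response_time(canonical_params(tau1=tau1)) == tau1

    def test_sixty_three_percent_of_span_reached_at_mrt(self):
        p = canonical_params()
        rise = evaluate(p.lam + mean_response_time(p), p, "log_logistic") - p.vo2_rest
        np.testing.assert_allclose(rise, (1 - np.exp(-1)) * (p.vo2_ss - p.vo2_rest), rtol=1e-12)


class TestKineticParams:
    @pytest.mark.parametrize(
        "overrides",
        [
            dict(vo2_rest=-1.0),
            dict(vo2_ss=200.0),          # below rest
            dict(vo2_rec=1500.0),        # above steady state
            dict(tau1=0.0),
            dict(t_half=0.0),
            dict(lam=100.0, lam_max=60.0),
        ],
    )
    def test_invariants_enforced(self, overrides):
        with pytest.raises(ValueError):
            canonical_params(**overrides).validate()
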