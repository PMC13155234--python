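"""Divergence-exponent estimator: embedding, neighbor search, slope fits."""

import numpy as np
import pytest

from gaitdyn.events import plan_bouts
from gaitdyn.lde import (
    DivergenceCurve,
    LdeParams,
    NormalizedBout,
    _neighbors_brute,
    _neighbors_kdtree,
    delay_embed,
    divergence_curve,
    fit_short_term_lde,
    lde_for_trial,
    time_normalize,
)
from gaitdyn.lyapunov import benettin_lle
from gaitdyn.series import AccelSeries
from gaitdyn.synthetic import simulate_lumbar_accel


def _periodic_trial(n_strides=92, stride_time=1.0):
    return simulate_lumbar_accel(
        [stride_time] * n_strides, amplitude_cv=0.0, sensor_noise_sd=0.0,
        sample_rate=128, seed=0,
    )


class TestTimeNormalize:
    def test_eight_strides_make_800_rows(self):
        accel, truth = _periodic_trial()
        nb = time_normalize(accel, truth.event_indices[:9])
        assert nb.samples.shape == (800, 3)
        assert nb.strides_per_bout == 8

    def test_identity_when_stride_is_100_samples(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((200, 3))
        accel = AccelSeries(samples=data, sample_rate=100)
        nb = time_normalize(accel, [0, 100], samples_per_stride=100)
        np.testing.assert_allclose(nb.samples, data[:100], atol=1e-12)

    def test_linear_ramp_preserved(self):
        t = np.arange(0, 260, dtype=float)
        accel = AccelSeries(samples=np.column_stack([t, 2 * t, -t]), sample_rate=128)
        nb = time_normalize(accel, [0, 130, 255], samples_per_stride=100)
        # stride 1 spans samples [0, 130): resampled ramp hits 0, 1.3, 2.6, ...
        expected1 = 130.0 * np.arange(100) / 100.0
        np.testing.assert_allclose(nb.samples[:100, 0], expected1, atol=1e-9)
        expected2 = 130.0 + 125.0 * np.arange(100) / 100.0
        np.testing.assert_allclose(nb.samples[100:, 0], expected2, atol=1e-9)
        np.testing.assert_allclose(nb.samples[:, 1], 2 * nb.samples[:, 0], atol=1e-9)

    def test_bad_events_rejected(self):
        accel, _ = _periodic_trial(10)
        with pytest.raises(ValueError, match="increasing"):
            time_normalize(accel, [0, 100, 100])
        with pytest.raises(ValueError, match="range"):
            time_normalize(accel, [0, accel.n_samples + 5])


class TestDelayEmbed:
    def test_default_dimensions(self):
        nb = NormalizedBout(samples=np.random.default_rng(0).standard_normal((800, 3)),
                            strides_per_bout=8)
        space = delay_embed(nb)
        assert space.states.shape == (750, 9)

    def test_ramp_state_contains_delayed_copies(self):
        t = np.arange(200, dtype=float)
        space = delay_embed(np.column_stack([t, t, t]), delay=25, copies=3)
        np.testing.assert_allclose(space.states[0], [0, 25, 50] * 3)

    def test_constant_signal_flagged_downstream(self):
        space = delay_embed(np.ones((400, 3)), delay=25, copies=3)
        with pytest.raises(ValueError, match="degenerate"):
            divergence_curve(space, theiler_window=50, horizon=50)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            delay_embed(np.ones((50, 3)), delay=25, copies=3)


class TestNeighborSearch:
    @pytest.mark.parametrize("theiler", [0, 5, 40])
    def test_accelerated_equals_brute_force(self, theiler):
        rng = np.random.default_rng(17)
        states = rng.standard_normal((300, 9))
        np.testing.assert_array_equal(
            _neighbors_kdtree(states, theiler), _neighbors_brute(states, theiler)
        )

    def test_agreement_on_embedded_gait_signal(self):
        accel, truth = simulate_lumbar_accel(
            [1.0] * 10, amplitude_cv=0.05, sensor_noise_sd=0.05, seed=3
        )
        nb = time_normalize(accel, truth.event_indices[:9])
        space = delay_embed(nb)
        states = space.states[:300]
        np.testing.assert_array_equal(
            _neighbors_kdtree(states, 100), _neighbors_brute(states, 100)
        )


class TestFitShortTerm:
    def test_exact_line(self):
        t = np.arange(101, dtype=float)
        curve = DivergenceCurve(t=t, mean_log_div=0.02 * t - 3.0)
        assert fit_short_term_lde(curve, window=50) == pytest.approx(2.0)

    def test_constant_curve(self):
        t = np.arange(101, dtype=float)
        curve = DivergenceCurve(t=t, mean_log_div=np.full(101, -2.0))
        assert fit_short_term_lde(curve, window=50) == pytest.approx(0.0)

    def test_halved_window_on_convex_curve_steeper(self):
        t = np.arange(101, dtype=float)
        # concave-down (saturating) curve: early slope exceeds late slope
        curve = DivergenceCurve(t=t, mean_log_div=np.log1p(t))
        full = fit_short_term_lde(curve, window=100)
        half = fit_short_term_lde(curve, window=50)
        assert half >= full

    def test_window_validation(self):
        t = np.arange(51, dtype=float)
        curve = DivergenceCurve(t=t, mean_log_div=t)
        with pytest.raises(ValueError, match="horizon"):
            fit_short_term_lde(curve, window=60)
        with pytest.raises(ValueError, match="2 points"):
            fit_short_term_lde(curve, window=0)


class TestTrialLevel:
    def test_periodic_signal_near_zero_exponent(self):
        accel, truth = _periodic_trial()
        ev = truth.event_indices[:-1]
        res = lde_for_trial(accel, ev, plan_bouts(ev, 11, 8))
        assert abs(res.lambda_s) <= 0.05

    def test_identical_bouts_equal_single_bout(self):
        accel, truth = _periodic_trial()
        ev = truth.event_indices[:-1]
        res = lde_for_trial(accel, ev, plan_bouts(ev, 11, 8))
        assert np.allclose(res.per_bout, res.per_bout[0], atol=1e-9)
        assert res.lambda_s == pytest.approx(res.per_bout[0], abs=1e-9)

    def test_scale_invariance(self):
        accel, truth = simulate_lumbar_accel(
            [1.0] * 92, amplitude_cv=0.05, sensor_noise_sd=0.05, seed=9
        )
        ev = truth.event_indices[:-1]
        plan = plan_bouts(ev, 11, 8)
        res1 = lde_for_trial(accel, ev, plan)
        scaled = AccelSeries(samples=7.3 * accel.samples,
                             sample_rate=accel.sample_rate)
        res2 = lde_for_trial(scaled, ev, plan)
        assert res2.lambda_s == pytest.approx(res1.lambda_s, abs=1e-6)

    def test_aggregate_modes(self):
        accel, truth = simulate_lumbar_accel(
            [1.0] * 92, amplitude_cv=0.05, sensor_noise_sd=0.05, seed=10
        )
        ev = truth.event_indices[:-1]
        plan = plan_bouts(ev, 11, 8)
        by_curves = lde_for_trial(accel, ev, plan, LdeParams(aggregate="curves"))
        by_slopes = lde_for_trial(accel, ev, plan, LdeParams(aggregate="slopes"))
        assert by_slopes.lambda_s == pytest.approx(by_curves.per_bout.mean())
        # the two aggregation orders agree closely but not exactly
        assert by_curves.lambda_s == pytest.approx(by_slopes.lambda_s, rel=0.2)


class TestBenettinOracle:
    def test_harmonic_oscillator_zero_exponent(self):
        lle = benettin_lle("harmonic", duration=50.0, dt=0.005, seed=0)
        assert abs(lle) < 1e-4

    def test_lorenz_positive_and_stable_across_seeds(self):
        a = benettin_lle("lorenz", duration=150.0, dt=0.005, seed=1)
        b = benettin_lle("lorenz", duration=150.0, dt=0.005, seed=2)
        assert 0.7 < a < 1.1
        assert a == pytest.approx(b, rel=0.1)
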