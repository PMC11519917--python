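"""Image-pair pipeline, calibration and RLD estimator tests."""

import numpy as np
import pytest

from lumistraddle import (
    CalibrationCurve,
    FramePair,
    KineticsParams,
    RLDConfig,
    TimingConfig,
    build_scene,
    fit_calibration,
    frame_integrals,
    integrated_decay_image,
    normalized_decay_image,
    o2_from_pn,
    predicted_calibration,
    render_pair,
    rld_lifetime,
    smooth_series,
)
from lumistraddle.exceptions import (
    CalibrationError,
    InputError,
    TimingMismatchError,
)
from lumistraddle.processing import (
    MASK_CLIPPED,
    MASK_GUARD,
    MASK_NONDECAYING,
    MASK_NONPOSITIVE,
    MASK_OUT_OF_RANGE,
    MASK_SATURATED,
    temporal_moving_average,
)


def _pair(dim, bright, timing=None, **kw):
    return FramePair(
        np.asarray(dim, dtype=float), np.asarray(bright, dtype=float),
        timing or TimingConfig(80.0, exposure=2000.0), **kw,
    )


class TestIntegratedDecayImage:
    def test_identical_frames_give_zero(self):
        img = np.full((4, 4), 100.0)
        p = integrated_decay_image(_pair(img, img))
        assert np.all(p.values == 0.0)
        assert np.all(p.valid)

    def test_common_background_cancels_exactly(self):
        # integer-valued counts, as camera data are: cancellation is exact
        rng = np.random.default_rng(0)
        dim = rng.integers(10, 50, (8, 8)).astype(float)
        bright = dim + rng.integers(0, 30, (8, 8))
        base = integrated_decay_image(_pair(dim, bright))
        shifted = integrated_decay_image(_pair(dim + 200.0, bright + 200.0))
        assert np.array_equal(base.values, shifted.values)

    def test_negative_difference_clipped_and_flagged(self):
        p = integrated_decay_image(_pair([[10.0]], [[4.0]]))
        assert p.values[0, 0] == 0.0
        assert p.reasons[0, 0] & MASK_CLIPPED

    def test_saturated_pixels_propagate(self):
        pair = _pair([[10.0, 255.0]], [[20.0, 255.0]], full_scale=255.0)
        p = integrated_decay_image(pair)
        assert not p.reasons[0, 0]
        assert p.reasons[0, 1] & MASK_SATURATED

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            _pair(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_mean_p_matches_forward_model(self, sensor):
        """Noiseless render at known lifetime reproduces the model P."""
        timing = TimingConfig(80.0, exposure=2000.0)
        scene = build_scene("uniform", (8, 8), o2=50.0)
        pair = render_pair(scene, sensor, timing)
        tau = sensor.lifetime(50.0)
        expected = frame_integrals(
            KineticsParams(decay_lifetime=tau, rise_time=tau), timing
        ).p
        measured = integrated_decay_image(pair).values.mean()
        assert measured == pytest.approx(expected, rel=0.01)


class TestNormalizedDecayImage:
    def test_homogeneous_of_degree_zero(self):
        # tripling both integer-count frames leaves P_N bit-identical
        rng = np.random.default_rng(1)
        dim = rng.integers(10, 50, (8, 8)).astype(float)
        bright = dim + rng.integers(0, 30, (8, 8))
        a = normalized_decay_image(_pair(dim, bright), guard_eps=1e-9)
        b = normalized_decay_image(_pair(3 * dim, 3 * bright), guard_eps=1e-9)
        assert np.array_equal(a.values, b.values)

    def test_dark_pixel_masked_not_infinite(self):
        pn = normalized_decay_image(_pair([[0.0, 20.0]], [[0.0, 40.0]]),
                                    guard_eps=1.0)
        assert pn.values[0, 0] == 0.0
        assert pn.reasons[0, 0] & MASK_GUARD
        assert np.isfinite(pn.values).all()

    def test_flat_despite_illumination_gradient(self, sensor):
        """P_N is uniform across a 5x excitation gradient (noiseless)."""
        timing = TimingConfig(80.0, exposure=2000.0)
        scene = build_scene("cuvette_gradient", (32, 16), o2=50.0)
        ratio = scene.illumination.max() / scene.illumination.min()
        assert ratio == pytest.approx(5.0, rel=1e-12)
        pn = normalized_decay_image(render_pair(scene, sensor, timing))
        spread = np.ptp(pn.values) / pn.values.mean()
        assert spread < 0.005


class TestFitCalibration:
    def test_two_point_from_published_style_values(self):
        cal = fit_calibration(
            np.array([1.58, 0.395]), np.array([0.0, 100.0]), method="two-point"
        )
        assert cal.ksv == pytest.approx(0.03, rel=1e-12)
        assert cal.pn0 == pytest.approx(1.58, rel=1e-12)

    def test_published_calibration_constants_are_valid(self):
        # planar-optode constants for 80 us pulses
        cal = CalibrationCurve(pn0=1.58, ksv=0.0391, r_squared=0.99)
        assert cal.o2(0.79) == pytest.approx((2.0 - 1.0) / 0.0391, rel=1e-12)

    def test_least_squares_recovers_model_curve_exactly(self, sensor):
        """Noiseless model P_N refits to the generator's apparent K_SV."""
        timing = TimingConfig(80.0)
        grid = np.array([0.0, 25.0, 50.0, 100.0, 200.0])
        pred = predicted_calibration(sensor, timing, grid)
        cal = fit_calibration(pred.p_n, grid, method="least-squares",
                              timing=timing)
        assert cal.ksv == pytest.approx(pred.ksv_apparent, abs=1e-10)
        assert cal.pn0 == pytest.approx(pred.pn0, abs=1e-10)

    def test_fewer_than_two_levels_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration(np.array([1.0]), np.array([0.0]))

    def test_missing_zero_level_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration(np.array([1.0, 0.5]), np.array([50.0, 100.0]))

    def test_non_monotone_pn_warns_but_fits(self):
        with pytest.warns(UserWarning):
            cal = fit_calibration(
                np.array([1.0, 0.6, 0.7, 0.4]),
                np.array([0.0, 30.0, 60.0, 100.0]),
            )
        assert cal.ksv > 0


class TestO2FromPn:
    def test_pn0_maps_to_zero(self):
        cal = CalibrationCurve(pn0=0.4, ksv=0.02)
        out = o2_from_pn(np.full((2, 2), 0.4), cal)
        assert np.all(out.o2 == 0.0)
        assert np.all(out.valid)

    def test_round_trip_at_400_percent(self, sensor):
        """Supersaturated O2 (beyond air saturation) inverts cleanly."""
        timing = TimingConfig(1240.0)  # complete excitation: linear regime
        grid = np.array([0.0, 100.0, 200.0, 400.0])
        pred = predicted_calibration(sensor, timing, grid)
        cal = fit_calibration(pred.p_n, grid, timing=timing)
        out = o2_from_pn(np.full((2, 2), pred.p_n[-1]), cal, timing=timing)
        assert out.o2[0, 0] == pytest.approx(400.0, abs=1e-6)

    def test_pn_above_pn0_flagged_as_zero(self):
        cal = CalibrationCurve(pn0=0.4, ksv=0.02)
        out = o2_from_pn(np.array([[0.5]]), cal)
        assert out.o2[0, 0] == 0.0
        assert out.reasons[0, 0] & MASK_OUT_OF_RANGE

    def test_nonpositive_pn_masked(self):
        cal = CalibrationCurve(pn0=0.4, ksv=0.02)
        out = o2_from_pn(np.array([[0.0, -0.1]]), cal)
        assert np.all(out.reasons & MASK_NONPOSITIVE)

    def test_timing_fingerprint_mismatch_refused(self):
        cal = CalibrationCurve(pn0=0.4, ksv=0.02,
                               timing_fingerprint=(80.0, 6.0, 2000.0))
        other = TimingConfig(160.0, exposure=2000.0, interframe=6.0)
        with pytest.raises(TimingMismatchError):
            o2_from_pn(np.full((2, 2), 0.2), cal, timing=other)
        out = o2_from_pn(np.full((2, 2), 0.2), cal, timing=other, force=True)
        assert np.all(out.valid)


class TestSmoothSeries:
    def test_constant_stack_unchanged(self):
        stack = np.full((5, 6, 6), 3.0)
        out, _ = smooth_series(stack)
        assert np.allclose(out, 3.0)

    def test_single_pixel_impulse_removed(self):
        stack = np.zeros((3, 9, 9))
        stack[1, 4, 4] = 100.0
        out, _ = smooth_series(stack)
        assert out[1, 4, 4] == 0.0

    def test_temporal_average_variance_reduction(self, rng):
        """3-point moving average cuts white-noise variance to ~1/3."""
        stack = rng.normal(0.0, 1.0, (300, 16, 16))
        smoothed = temporal_moving_average(stack)
        ratio = smoothed[1:-1].var() / stack.var()
        assert ratio == pytest.approx(1.0 / 3.0, rel=0.05)

    def test_short_stack_warns_and_skips_temporal(self):
        with pytest.warns(UserWarning):
            out, _ = smooth_series(np.zeros((2, 6, 6)))
        assert out.shape == (2, 6, 6)

    def test_mask_propagates_by_majority(self):
        stack = np.zeros((3, 7, 7))
        invalid = np.zeros((3, 7, 7), dtype=bool)
        invalid[:, 2:5, 2:5] = True  # persistent 3x3 bad patch
        invalid[:, 0, 0] = False
        invalid[1, 6, 6] = True  # transient single-frame outlier
        _, out_invalid = smooth_series(stack, invalid)
        assert out_invalid[1, 3, 3]  # patch center cannot be repaired
        assert not out_invalid[1, 6, 6]  # outvoted in time
        assert not out_invalid[1, 0, 0]


class TestRLDLifetime:
    def test_gate_ratio_e_gives_separation(self):
        cfg = RLDConfig(gate1_delay=41.0, gate2_delay=47.0)
        f1 = np.full((2, 2), np.e)
        f2 = np.full((2, 2), 1.0)
        out = rld_lifetime(f1, f2, RLDConfig(0.0, 6.0))
        assert np.allclose(out.values, 6.0)
        assert cfg.separation == -6.0

    def test_recovers_62us_from_41_47_gates(self):
        """Gates at 41 and 47 us on exp(-t/62) give tau = 62 exactly."""
        cfg = RLDConfig(gate1_delay=41.0, gate2_delay=47.0)
        f1 = np.exp(-41.0 / 62.0) * np.ones((3, 3))
        f2 = np.exp(-47.0 / 62.0) * np.ones((3, 3))
        out = rld_lifetime(f1, f2, cfg)
        assert np.allclose(out.values, 62.0)
        assert np.all(out.valid)

    def test_equal_gates_masked(self):
        out = rld_lifetime(np.ones((2, 2)), np.ones((2, 2)),
                           RLDConfig(41.0, 47.0))
        assert not out.valid.any()
        assert np.all(out.reasons & MASK_NONDECAYING)

    def test_nonpositive_gates_masked(self):
        out = rld_lifetime(np.array([[0.0]]), np.array([[1.0]]),
                           RLDConfig(41.0, 47.0))
        assert out.reasons[0, 0] & MASK_NONPOSITIVE

    def test_rising_signal_masked(self):
        # brighter at the later gate: not a decay
        out = rld_lifetime(np.array([[1.0]]), np.array([[2.0]]),
                           RLDConfig(41.0, 47.0))
        assert not out.valid[0, 0]


class TestRankOrderAgreement:
    def test_pn_and_rld_both_monotone_across_o2(self, sensor):
        """Both lifetime readouts rank an O2 gradient identically."""
        timing = TimingConfig(80.0, exposure=2000.0)
        o2_levels = np.linspace(0.0, 200.0, 9)
        pn, tau_rld = [], []
        cfg = RLDConfig(gate1_delay=41.0, gate2_delay=47.0)
        for o2 in o2_levels:
            pair = render_pair(build_scene("uniform", (4, 4), o2=float(o2)),
                               sensor, timing)
            pn.append(float(normalized_decay_image(pair).values.mean()))
            tau = sensor.lifetime(float(o2))
            f1 = np.exp(-41.0 / tau) * np.ones((2, 2))
            f2 = np.exp(-47.0 / tau) * np.ones((2, 2))
            tau_rld.append(float(rld_lifetime(f1, f2, cfg).values.mean()))
        assert np.all(np.diff(pn) < 0)
        assert np.all(np.diff(tau_rld) < 0)
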