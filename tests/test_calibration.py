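import dataclasses

import numpy as np
import pytest

from ivmquant import (
    CalibrationError,
    CalibrationSet,
    ConfigurationError,
    StructuralError,
    calibrate_session,
    calibration_factor,
    flatfield_correct,
    subtract_background,
    subtract_dark,
)
from ivmquant.calibration import CHAIN_STEPS
from ivmquant.simulator import SimulationConfig, simulate_session


class TestSubtractions:
    def test_scalar_dark(self):
        out = subtract_dark(np.array([[10.0, 12.0], [14.0, 16.0]]), 10.0)
        np.testing.assert_array_equal(out, [[0.0, 2.0], [4.0, 6.0]])

    def test_pixelwise_identity_cancellation(self):
        f = np.arange(9.0).reshape(3, 3)
        np.testing.assert_array_equal(subtract_dark(f, f), np.zeros((3, 3)))

    def test_negatives_retained(self):
        np.testing.assert_array_equal(subtract_dark(np.array([[5.0]]), 8.0), [[-3.0]])

    def test_background_scalar(self):
        out = subtract_background(np.array([[100.0, 100.0]]), 40.0)
        np.testing.assert_array_equal(out, [[60.0, 60.0]])

    def test_background_self_subtraction(self):
        pre = np.random.default_rng(1).random((4, 4))
        assert np.all(subtract_background(pre, pre) == 0)

    def test_shape_mismatch(self):
        with pytest.raises(StructuralError):
            subtract_dark(np.zeros((3, 3)), np.zeros((2, 2)))

    def test_varying_autofluorescence_nulls_to_noise_floor(self, rng):
        # spatially structured autofluorescence + shot noise; subtracting the
        # pixelwise pre-injection mean leaves a residual mean ~ 0
        h, w = 100, 100
        auto = 20.0 + 5.0 * rng.random((h, w))
        n_pre = 8
        pre = auto + rng.normal(0, 1.0, (n_pre, h, w))
        frame = auto + rng.normal(0, 1.0, (h, w))
        residual = subtract_background(frame, pre.mean(axis=0))
        se = 1.0 * np.sqrt(1 + 1 / n_pre) / np.sqrt(h * w)
        assert abs(residual.mean()) < 3 * se


class TestFlatField:
    def test_self_correction_yields_flat_field(self, rng):
        phantom = 100.0 + 10.0 * rng.random((20, 20))
        out = flatfield_correct(phantom, phantom, smooth_sigma=0)
        np.testing.assert_allclose(out, phantom.mean(), rtol=1e-12)

    def test_constant_phantom_is_identity(self, rng):
        frame = rng.random((10, 10))
        np.testing.assert_allclose(
            flatfield_correct(frame, np.full((10, 10), 7.0)), frame, rtol=1e-12
        )

    def test_idempotent_under_constant_phantom(self, rng):
        frame = rng.random((8, 8))
        once = flatfield_correct(frame, np.full((8, 8), 3.0))
        twice = flatfield_correct(once, np.full((8, 8), 3.0))
        np.testing.assert_array_equal(once, twice)

    def test_analytic_vignette_inverts_to_uniform(self):
        # uniform scene x Gaussian vignette, corrected with the noiseless
        # vignette itself -> coefficient of variation at machine precision
        h, w = 60, 80
        y, x = np.mgrid[0:h, 0:w]
        v = np.exp(-((y - h / 2) ** 2 + (x - w / 2) ** 2) / (2 * 40.0**2))
        scene = 50.0 * v
        out = flatfield_correct(scene, v, smooth_sigma=0)
        assert out.std() / out.mean() < 1e-6

    def test_nonpositive_phantom_rejected(self):
        phantom = np.ones((5, 5))
        phantom[2, 2] = -1.0
        with pytest.raises(CalibrationError):
            flatfield_correct(np.ones((5, 5)), phantom, smooth_sigma=0)


class TestCalibrationFactor:
    def test_ratio_definition(self):
        assert calibration_factor(np.full((4, 4), 50.0), 100.0) == pytest.approx(2.0)
        assert calibration_factor(np.full((4, 4), 80.0), 80.0) == pytest.approx(1.0)

    def test_roi_restriction(self):
        frame = np.zeros((4, 4))
        frame[:2] = 10.0
        roi = np.zeros((4, 4), bool)
        roi[:2] = True
        assert calibration_factor(frame, 20.0, roi=roi) == pytest.approx(2.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(CalibrationError):
            calibration_factor(np.zeros((3, 3)), 1.0)


class TestCalibrateSession:
    def test_noiseless_forward_model_inverts_exactly(self, noiseless_config):
        stack, cal, truth = simulate_session(noiseless_config, seed=3)
        out = calibrate_session(stack, cal, phantom_smooth_sigma=0)
        for i in range(len(out)):
            np.testing.assert_allclose(
                out.frames[i], truth.calibrated_frame(i), rtol=1e-9, atol=1e-12
            )

    def test_background_scene_calibrates_to_zero(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, amplitude_mean=0.0)
        stack, cal, _ = simulate_session(cfg, seed=4)
        out = calibrate_session(stack, cal, phantom_smooth_sigma=0)
        np.testing.assert_allclose(out.frames, 0.0, atol=1e-12)

    def test_gain_invariance_noiseless(self, noiseless_config):
        outs = []
        for gain in (1.0, 2.0):
            cfg = dataclasses.replace(noiseless_config, gain=gain)
            stack, cal, _ = simulate_session(cfg, seed=5)
            outs.append(calibrate_session(stack, cal, phantom_smooth_sigma=0).frames)
        np.testing.assert_allclose(outs[0], outs[1], rtol=1e-12, atol=1e-14)

    def test_gain_invariance_with_shot_noise(self, small_config):
        # calibrated frame means agree within 1% across a 2x gain change
        # (session-level calibration noise is common-mode, so a relative
        # tolerance is the meaningful bound here)
        means = []
        for gain in (1.0, 2.0):
            cfg = dataclasses.replace(small_config, gain=gain, texture_sd=0.0)
            stack, cal, _ = simulate_session(cfg, seed=6)
            out = calibrate_session(stack, cal)
            means.append(out.frames[-1].mean())
        assert abs(means[0] - means[1]) / means[0] < 0.01

    def test_background_nulling_in_expectation(self, small_config):
        # probe-free session: calibrated mean over >=1e4 pixels within 3 SE of 0
        cfg = dataclasses.replace(
            small_config, amplitude_mean=0.0, texture_sd=0.0, image_shape=(100, 105)
        )
        stack, cal, _ = simulate_session(cfg, seed=7)
        out = calibrate_session(stack, cal)
        px = out.frames[-1].ravel()
        assert px.size >= 10_000
        se = px.std(ddof=1) / np.sqrt(px.size)
        assert abs(px.mean()) < 3 * se

    def test_provenance_order(self, noiseless_config):
        stack, cal, _ = simulate_session(noiseless_config, seed=8)
        out = calibrate_session(stack, cal)
        assert out.provenance == CHAIN_STEPS == ("dark", "background", "flatfield", "standard")

    def test_missing_phantom_names_component(self, noiseless_config):
        stack, cal, _ = simulate_session(noiseless_config, seed=9)
        broken = dataclasses.replace(cal, phantom=None)
        with pytest.raises(ConfigurationError, match="phantom"):
            calibrate_session(stack, broken)

    def test_preinjection_frames_consumed(self, noiseless_config):
        stack, cal, _ = simulate_session(noiseless_config, seed=10)
        out = calibrate_session(stack, cal)
        assert len(out) == len(noiseless_config.times_min)
        assert np.all(out.times_min >= 0)

    def test_background_after_flatfield_mode_nulls_background(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, amplitude_mean=0.0)
        stack, cal, _ = simulate_session(cfg, seed=11)
        out = calibrate_session(
            stack, cal, background_after_flatfield=True, phantom_smooth_sigma=0
        )
        np.testing.assert_allclose(out.frames, 0.0, atol=1e-10)
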