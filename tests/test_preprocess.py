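"""Image-correction chain: alignment, deconvolution, baseline, denoise,
background, ΔF/F0."""

import numpy as np
import pytest
from scipy import ndimage, stats

from optoquant.preprocess import (apply_baseline, compute_dff, denoise_traces,
                                  fit_baseline, gaussian_psf,
                                  landweber_deconvolve, movement_scores,
                                  preprocess_movie, register_translation,
                                  subtract_background)


class TestRegistration:
    def test_known_shift_recovered(self, structured_image):
        shifted = ndimage.shift(structured_image, (3.0, -2.0), order=3,
                                mode="nearest")
        stack = np.stack([structured_image, shifted])
        res = register_translation(stack)
        # estimated shift undoes the applied one
        assert np.allclose(res.shifts[1], (-3.0, 2.0), atol=0.1)
        assert not res.flagged[1]

    def test_identical_frames_zero_shift(self, structured_image):
        stack = np.stack([structured_image] * 4)
        res = register_translation(stack)
        assert np.allclose(res.shifts, 0.0)
        assert np.allclose(res.aligned, stack)

    def test_idempotence(self, structured_image, rng):
        stack = np.stack([
            structured_image,
            ndimage.shift(structured_image, (1.5, -0.5), mode="nearest"),
            ndimage.shift(structured_image, (-1.0, 2.0), mode="nearest"),
        ]) + rng.normal(0, 1.0, (3, 64, 64))
        once = register_translation(stack)
        twice = register_translation(once.aligned)
        assert np.abs(twice.shifts).max() <= 0.05

    def test_pure_noise_frames_are_flagged_not_fatal(self, rng):
        stack = rng.normal(0, 1.0, (3, 32, 32))
        res = register_translation(stack)
        assert res.flagged[1:].all()
        assert res.aligned.shape == stack.shape

    def test_needs_two_frames(self, structured_image):
        with pytest.raises(ValueError):
            register_translation(structured_image[None])


class TestMovementScores:
    def test_static_movie_scores_zero(self, structured_image):
        stack = np.stack([structured_image] * 6)
        diag = movement_scores(stack, stim_window=(2, 5))
        assert np.allclose(diag.scores, 0.0)
        assert diag.amms == 0.0

    def test_rigid_shift_magnitude(self, structured_image):
        d = 2.0
        stack = np.stack([structured_image] * 4)
        stack[2] = ndimage.shift(structured_image, (d, 0.0), mode="nearest")
        diag = movement_scores(stack, stim_window=(1, 4))
        assert diag.scores[2] == pytest.approx(d, rel=0.35)
        assert diag.amms == pytest.approx(d, rel=0.35)

    def test_jitter_confined_to_stim_window(self, structured_image):
        amp = 1.0
        frames = [structured_image] * 4
        for ph in range(4):
            frames.append(ndimage.shift(
                structured_image, (amp * np.sin(np.pi * (ph + 1) / 4), 0.0),
                mode="nearest"))
        diag = movement_scores(np.stack(frames), stim_window=(4, 8))
        assert diag.amms == pytest.approx(amp, rel=0.35)

    def test_empty_window_raises(self, structured_image):
        with pytest.raises(ValueError, match="empty"):
            movement_scores(np.stack([structured_image] * 3), (2, 2))


class TestLandweber:
    def test_delta_psf_fixed_point(self, rng):
        img = rng.random((24, 24)) * 100
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        res = landweber_deconvolve(img, delta, n_iter=10)
        assert np.allclose(res.stack, img, atol=1e-8)

    def test_blurred_point_source_sharpens_monotonically(self, psf_small):
        img = np.zeros((32, 32))
        img[16, 16] = 100.0
        blurred = ndimage.gaussian_filter(img, 1.5)
        res = landweber_deconvolve(blurred, psf_small, n_iter=50)
        assert res.stack.max() > blurred.max()
        assert (np.diff(res.residual_mse) <= 1e-12).all()
        assert (res.stack >= 0).all()

    def test_invalid_inputs(self, psf_small, rng):
        img = rng.random((16, 16))
        with pytest.raises(ValueError, match="psf"):
            landweber_deconvolve(img, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="step"):
            landweber_deconvolve(img, psf_small, step=10.0)


class TestBaseline:
    def test_flat_trace_unit_factors(self):
        stack = np.full((60, 4, 4), 500.0)
        model = fit_baseline(stack, (0, 15), (45, 60))
        assert np.allclose(model.factors, 1.0, atol=1e-3)

    def test_single_exponential_flattened(self):
        t = np.arange(200) / 10.0
        trace = 800.0 * np.exp(-t / 50.0)
        stack = np.tile(trace[:, None, None], (1, 3, 3))
        model = fit_baseline(stack, (0, 30), (170, 200))
        corrected = apply_baseline(stack, model)
        ctl = np.r_[corrected[:30, 1, 1], corrected[170:, 1, 1]]
        slope = stats.linregress(np.r_[t[:30], t[170:]], ctl).slope
        # residual drift below 1% of F0 per 100 s
        assert abs(slope) * 100.0 < 0.01 * 800.0

    def test_two_term_decay_recovered_on_controls(self):
        t = np.arange(220) / 10.0
        trace = 1000.0 * (0.8 * np.exp(-t / 30.0) + 0.2 * np.exp(-t / 300.0))
        stack = np.tile(trace[:, None, None], (1, 2, 2))
        model = fit_baseline(stack, (0, 40), (180, 220))
        a, b, c, d = model.coefs[0, 0]
        fitted = a * np.exp(b * t) + c * np.exp(d * t)
        ctl = np.r_[np.arange(0, 40), np.arange(180, 220)]
        rms = np.sqrt(np.mean((fitted[ctl] - trace[ctl]) ** 2))
        assert rms < 0.01 * trace[ctl].mean()


class TestDenoise:
    def test_constant_trace_unchanged(self):
        stack = np.full((40, 2, 2), 7.0)
        assert np.allclose(denoise_traces(stack, span=9), stack)

    def test_white_noise_suppression(self, rng):
        stack = 100.0 + rng.normal(0, 4.0, (120, 3, 3))
        out = denoise_traces(stack, span=15)
        assert out[:, 1, 1].std() < 2.0  # < sigma/2

    def test_peak_preservation(self):
        # stimulus-locked response: fast step, slow sensor decay
        t = np.arange(80) / 10.0
        trace = np.where(t >= 3.0, np.exp(-(t - 3.0) / 8.96), 0.0)
        out = denoise_traces(trace[:, None, None], span=15)[:, 0, 0]
        assert out.max() >= 0.8 * trace.max()

    def test_span_validation(self):
        stack = np.zeros((20, 2, 2))
        with pytest.raises(ValueError):
            denoise_traces(stack, span=2)
        with pytest.raises(ValueError):
            denoise_traces(stack, span=20)


class TestBackground:
    def test_constant_offset_invariance(self, rng):
        stack = rng.random((10, 8, 8)) * 50
        mask = np.zeros((8, 8), bool)
        mask[:, :2] = True
        base = subtract_background(stack, mask)
        shifted = subtract_background(stack + 100.0, mask)
        assert np.allclose(base, shifted)

    def test_time_varying_background_removed(self, rng):
        b_t = 10.0 * np.sin(np.arange(20) / 3.0) + 30.0
        stack = np.tile(b_t[:, None, None], (1, 6, 6))
        mask = np.zeros((6, 6), bool)
        mask[0] = True
        out = subtract_background(stack, mask)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty"):
            subtract_background(np.zeros((3, 4, 4)), np.zeros((4, 4), bool))


class TestDff:
    def test_reference_values(self):
        stack = np.full((12, 2, 2), 200.0)
        stack[6:] = 201.0
        res = compute_dff(stack, (0, 6))
        assert np.allclose(res.dff[:6], 0.0)
        assert np.allclose(res.dff[6:], 0.005)
        stack2 = np.concatenate([np.full((5, 2, 2), 100.0),
                                 np.full((5, 2, 2), 200.0)])
        assert np.allclose(compute_dff(stack2, (0, 5)).dff[5:], 1.0)

    def test_low_f0_pixels_masked(self):
        stack = np.full((10, 3, 3), 400.0)
        stack[:, 0, 0] = 1.0   # far below 5% of median F0
        res = compute_dff(stack, (0, 5))
        assert not res.mask[0, 0]
        assert np.isnan(res.dff[:, 0, 0]).all()

    def test_zero_f0_raises(self):
        with pytest.raises(ValueError):
            compute_dff(np.zeros((6, 2, 2)), (0, 3))


def test_pipeline_records_canonical_order(rng):
    stack = 1000.0 + rng.normal(0, 5.0, (30, 16, 16))
    mask = np.zeros((16, 16), bool)
    mask[:, :2] = True
    res = preprocess_movie(stack, f0_window=(0, 8), psf=gaussian_psf(1.0),
                           n_iter=5, denoise_span=9, background_mask=mask)
    assert res.order == ["align", "deconvolve", "denoise", "background", "dff"]
    full = preprocess_movie(stack, f0_window=(0, 8), psf=gaussian_psf(1.0),
                            n_iter=2, baseline_windows=((0, 8), (22, 30)))
    assert full.order == ["align", "deconvolve", "baseline", "dff"]
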