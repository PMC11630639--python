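"""Registration, deinterleaving, leakage, field and background corrections."""

import numpy as np
import pytest

from tirftrace.preprocess import (
    MovieStack,
    RegistrationParams,
    correct_autofluorescence,
    correct_leakage,
    correct_uneven_field,
    deinterleave,
    estimate_leakage,
    interleave,
    register,
)


def gaussian_image(shape, center, sigma=3.0, amp=100.0):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


class TestRegister:
    def test_identity_is_exact(self, rng):
        stack = MovieStack(rng.normal(size=(3, 32, 32)), 0.1)
        out = register(stack, RegistrationParams())
        assert np.array_equal(out.frames, stack.frames)

    def test_translation_moves_centroid(self):
        img = np.zeros((1, 41, 41))
        img[0, 20, 20] = 1.0
        stack = MovieStack(img, 0.1)
        out = register(stack, RegistrationParams(translation_px=(2, -3)))
        r, c = np.unravel_index(np.argmax(out.frames[0]), (41, 41))
        assert (r, c) == (22, 17)

    def test_round_trip_on_smooth_image(self):
        img = gaussian_image((64, 64), (30, 34), sigma=6.0)[None]
        stack = MovieStack(img, 0.1)
        p = RegistrationParams(rotation_deg=4.0, translation_px=(1.5, -2.5))
        back = register(register(stack, p), p.inverse())
        interior = (slice(0, 1), slice(10, 54), slice(10, 54))
        # two bilinear warps each smooth the peak slightly; allow 2% of amp
        assert np.max(np.abs(back.frames[interior] - img[interior])) < 2.0

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            RegistrationParams(rotation_deg=np.nan)


class TestDeinterleave:
    def test_channel_counts_and_interval(self, rng):
        g = MovieStack(rng.normal(size=(4, 8, 8)), 0.1, "green_cam")
        r = MovieStack(rng.normal(size=(4, 8, 8)), 0.1, "red_cam")
        chans = deinterleave(g, r)
        assert all(chans[k].n_frames == 2 for k in chans)
        assert chans["venus"].frame_interval_s == pytest.approx(0.2)

    def test_parity_slicing_by_constant_values(self):
        # distinct constant per (camera, excitation): slicing must be pure
        g = MovieStack(np.stack([np.full((4, 4), v) for v in [1, 2, 1, 2]]), 0.1)
        r = MovieStack(np.stack([np.full((4, 4), v) for v in [3, 4, 3, 4]]), 0.1)
        chans = deinterleave(g, r, parity="even")
        assert np.all(chans["venus"].frames == 1)
        assert np.all(chans["blank"].frames == 2)
        assert np.all(chans["mixed"].frames == 3)
        assert np.all(chans["rhodamine"].frames == 4)

    def test_round_trip(self, rng):
        g = MovieStack(rng.normal(size=(6, 5, 5)), 0.1, "green_cam")
        r = MovieStack(rng.normal(size=(6, 5, 5)), 0.1, "red_cam")
        g2, r2 = interleave(deinterleave(g, r))
        assert np.allclose(g2.frames, g.frames)
        assert np.allclose(r2.frames, r.frames)
        assert g2.frame_interval_s == pytest.approx(0.1)

    def test_mismatched_frame_counts_rejected(self, rng):
        g = MovieStack(rng.normal(size=(4, 4, 4)), 0.1)
        r = MovieStack(rng.normal(size=(6, 4, 4)), 0.1)
        with pytest.raises(ValueError):
            deinterleave(g, r)


class TestLeakage:
    def make_pair(self, leak, n=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = gaussian_image((32, 32), (16, 16), sigma=1.0, amp=500.0)
        venus = np.stack([base * (1 + 0.1 * i) for i in range(n)])
        mixed = leak * venus
        if noise:
            venus = venus + rng.normal(0, noise, venus.shape)
            mixed = mixed + rng.normal(0, noise, mixed.shape)
        return (
            MovieStack(venus, 0.2, "venus"),
            MovieStack(mixed, 0.2, "mixed"),
            [(16, 16)],
        )

    def test_noiseless_ratio_is_exact(self):
        venus, mixed, rois = self.make_pair(0.25)
        assert estimate_leakage(venus, mixed, rois) == pytest.approx(0.25, abs=1e-12)

    def test_zero_leakage_estimates_zero(self):
        venus, mixed, rois = self.make_pair(0.0, noise=0.5, seed=1)
        assert abs(estimate_leakage(venus, mixed, rois)) < 0.01

    def test_scale_invariance(self):
        venus, mixed, rois = self.make_pair(0.1, noise=1.0, seed=2)
        est1 = estimate_leakage(venus, mixed, rois)
        est2 = estimate_leakage(
            venus.with_frames(7.0 * venus.frames),
            mixed.with_frames(7.0 * mixed.frames),
            rois,
        )
        assert est2 == pytest.approx(est1, rel=1e-9)

    def test_zero_venus_intensity_rejected(self):
        venus = MovieStack(np.zeros((4, 16, 16)), 0.2, "venus")
        mixed = MovieStack(np.ones((4, 16, 16)), 0.2, "mixed")
        with pytest.raises(ValueError):
            estimate_leakage(venus, mixed, [(8, 8)])

    def test_correction_recovers_fret_term_exactly(self, rng):
        venus = MovieStack(rng.uniform(0, 100, (5, 16, 16)), 0.2, "venus")
        fret_true = rng.uniform(0, 10, (5, 16, 16))
        mixed = MovieStack(0.1 * venus.frames + fret_true, 0.2, "mixed")
        fret = correct_leakage(mixed, venus, 0.1)
        assert np.allclose(fret.frames, fret_true)
        assert fret.channel_tag == "fret"

    def test_correction_is_linear_per_frame(self, rng):
        v1 = MovieStack(rng.uniform(0, 10, (3, 8, 8)), 0.2, "venus")
        v2 = MovieStack(rng.uniform(0, 10, (3, 8, 8)), 0.2, "venus")
        m1 = MovieStack(rng.uniform(0, 10, (3, 8, 8)), 0.2, "mixed")
        m2 = MovieStack(rng.uniform(0, 10, (3, 8, 8)), 0.2, "mixed")
        lhs = correct_leakage(
            m1.with_frames(m1.frames + m2.frames),
            v1.with_frames(v1.frames + v2.frames),
            0.1,
        )
        rhs = correct_leakage(m1, v1, 0.1).frames + correct_leakage(m2, v2, 0.1).frames
        assert np.allclose(lhs.frames, rhs)


class TestUnevenField:
    def test_flat_image_maps_to_zero(self):
        out = correct_uneven_field(np.full((128, 128), 37.0))
        assert np.max(np.abs(out)) < 1e-6

    def test_spot_integral_preserved(self):
        img = np.full((128, 128), 20.0) + gaussian_image((128, 128), (64, 64),
                                                         sigma=0.74, amp=300.0)
        out = correct_uneven_field(img)
        spot_integral = gaussian_image((128, 128), (64, 64), 0.74, 300.0)[59:70, 59:70].sum()
        got = out[59:70, 59:70].sum()
        assert abs(got - spot_integral) / spot_integral < 0.05

    def test_gradient_removed(self):
        xx = np.arange(256)[None, :] * np.ones((256, 1))
        grad = 50.0 * xx / 255
        out = correct_uneven_field(grad + 100.0)
        assert np.sqrt(np.mean((out - out.mean()) ** 2)) < 0.05 * 50.0


class TestAutofluorescence:
    def make_stack(self, a1, k1, a2, k2, c, n=300, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * 0.2
        decay = a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t) + c
        frames = np.tile(decay[:, None, None], (1, 24, 24))
        if noise:
            frames = frames + rng.normal(0, noise, frames.shape)
        return MovieStack(frames, 0.2, "venus")

    def test_constant_background_recovered(self):
        stack = self.make_stack(0, 1, 0, 1, 50.0, noise=0.5, seed=3)
        out, fit = correct_autofluorescence(stack)
        assert abs(fit.evaluate(np.array([0.0]))[0] - 50.0) < 1.0
        assert abs(out.frames.mean()) < 0.5

    def test_injected_rates_recovered_within_ten_percent(self):
        stack = self.make_stack(40.0, 0.5, 20.0, 0.05, 10.0, noise=0.3, seed=4)
        out, fit = correct_autofluorescence(stack)
        ks = sorted([fit.k1, fit.k2], reverse=True)
        assert abs(ks[0] - 0.5) / 0.5 < 0.10
        assert abs(ks[1] - 0.05) / 0.05 < 0.10
        # corrected stack is centered on zero
        assert abs(out.frames.mean()) < 0.5

    def test_roi_pixels_excluded_from_fit_but_corrected(self):
        stack = self.make_stack(30.0, 0.4, 10.0, 0.04, 5.0, noise=0.2, seed=5)
        roi_mask = np.zeros((24, 24), dtype=bool)
        roi_mask[10:15, 10:15] = True
        stack.frames[:, roi_mask] += 500.0  # bright spots must not bias the fit
        out, fit = correct_autofluorescence(stack, roi_mask)
        ks = sorted([fit.k1, fit.k2], reverse=True)
        assert abs(ks[0] - 0.4) / 0.4 < 0.10
        assert abs(out.frames[:, ~roi_mask].mean()) < 0.5
        assert out.frames[:, roi_mask].mean() == pytest.approx(500.0, abs=1.0)

    def test_too_few_frames_rejected(self, rng):
        stack = MovieStack(rng.normal(size=(5, 8, 8)), 0.2)
        with pytest.raises(ValueError):
            correct_autofluorescence(stack)

    def test_frame_count_and_times_preserved(self):
        stack = self.make_stack(10, 0.3, 5, 0.03, 2, n=120, noise=0.1)
        out, _ = correct_autofluorescence(stack)
        assert out.n_frames == stack.n_frames
        assert np.allclose(out.frame_times, stack.frame_times)
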