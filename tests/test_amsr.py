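"""Retinex enhancement: kernel, illumination, weighting and merge contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leafclar.amsr import (
    EnhancementConfig, WeightField,
    build_surround_kernel, enhance, estimate_incident, frequency_weight,
    local_std_map, merge_and_compensate, msr_reflectance,
)
from leafclar.image import RgbImage
from leafclar.synth import generate_image
from leafclar.data import LABELS


def spatial_convolve_oracle(channel, taps):
    """Brute-force O(H*W*k^2) reflect-padded convolution."""
    r = taps.shape[0] // 2
    padded = np.pad(channel, r, mode="reflect")
    out = np.zeros_like(channel, dtype=float)
    flipped = taps[::-1, ::-1]
    for i in range(channel.shape[0]):
        for j in range(channel.shape[1]):
            out[i, j] = (padded[i:i + 2 * r + 1, j:j + 2 * r + 1] * flipped).sum()
    return out


class TestSurroundKernel:
    def test_center_tap_matches_gaussian_at_origin(self):
        k = build_surround_kernel(1.0, 3)
        raw_center = 1.0 / (2 * np.pi)  # formula value before renormalization
        # reconstruct pre-normalization center from ratios
        ratio = k.taps[3, 3] / k.taps.sum()
        assert k.taps[3, 3] == k.taps.max()
        unnorm = np.exp(0.0) / (2 * np.pi)
        assert abs(unnorm - raw_center) < 1e-12

    @given(sigma=st.floats(0.5, 50), radius=st.integers(1, 12))
    def test_taps_sum_to_one(self, sigma, radius):
        k = build_surround_kernel(sigma, radius)
        assert abs(k.taps.sum() - 1.0) < 1e-12
        assert (k.taps >= 0).all()
        np.testing.assert_allclose(k.taps, k.taps[::-1, ::-1])  # radial symmetry

    def test_large_sigma_is_nearly_uniform(self):
        k = build_surround_kernel(100.0, 3)
        assert k.taps.max() / k.taps.min() < 1.001

    @pytest.mark.parametrize("sigma,radius", [(0, 3), (-1, 3), (1, 0)])
    def test_invalid_parameters(self, sigma, radius):
        with pytest.raises(ValueError):
            build_surround_kernel(sigma, radius)


class TestIncidentEstimation:
    def test_constant_channel_is_fixed_point(self):
        k = build_surround_kernel(2.0, 5)
        c = np.full((16, 16), 0.37)
        np.testing.assert_allclose(estimate_incident(c, k), 0.37, atol=1e-9)

    def test_linearity_in_the_input(self, rng):
        k = build_surround_kernel(2.0, 5)
        s = rng.random((12, 12))
        np.testing.assert_allclose(estimate_incident(2 * s, k),
                                   2 * estimate_incident(s, k), atol=1e-9)

    def test_matches_bruteforce_spatial_convolution(self, rng):
        k = build_surround_kernel(2.0, 5)
        s = rng.random((16, 16))
        np.testing.assert_allclose(estimate_incident(s, k),
                                   spatial_convolve_oracle(s, k.taps), atol=1e-6)

    def test_fft_and_direct_paths_agree(self, rng):
        """The frequency-domain path equals direct convolution on 32x32."""
        s = rng.random((32, 32))
        k_fft = build_surround_kernel(9.0, 10)     # above the FFT threshold
        assert k_fft.sigma >= 8.0
        direct = spatial_convolve_oracle(s, k_fft.taps)
        np.testing.assert_allclose(estimate_incident(s, k_fft), direct, atol=1e-6)

    def test_kernel_larger_than_image_rejected(self):
        k = build_surround_kernel(2.0, 20)
        with pytest.raises(ValueError):
            estimate_incident(np.zeros((8, 8)), k)

    def test_output_within_input_range(self, rng):
        k = build_surround_kernel(3.0, 7)
        s = rng.random((20, 20))
        out = estimate_incident(s, k)
        assert out.min() >= s.min() - 1e-12 and out.max() <= s.max() + 1e-12


class TestLocalStd:
    def test_constant_channel_gives_zero_map(self):
        assert local_std_map(np.full((10, 10), 3.3), 3).max() < 1e-7

    def test_single_one_in_window(self):
        c = np.zeros((9, 9))
        c[4, 4] = 1.0
        out = local_std_map(c, 3)
        assert abs(out[4, 4] - np.sqrt(8.0) / 9.0) < 1e-12

    def test_checkerboard_interior_translation_invariance(self):
        c = np.indices((12, 12)).sum(axis=0) % 2
        out = local_std_map(c.astype(float), 3)
        interior = out[1:-1, 1:-1]
        # brute-force oracle on one interior window
        win = c[0:3, 0:3].astype(float)
        expected = win.std()
        np.testing.assert_allclose(interior, expected, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            local_std_map(np.zeros((5, 5)), 4)


class TestFrequencyWeight:
    def test_zero_sigma_gives_fully_homogeneous_profile(self):
        wf = frequency_weight(np.zeros((4, 4)), a1=2 / np.pi, a2=0.0)
        # A = (2/pi) * arccot(0) = 1 exactly -> homogeneous profile
        np.testing.assert_allclose(wf.weights[:, 0, 0], [0.2, 0.3, 0.5], atol=1e-12)

    @given(st.floats(0, 100), st.floats(-0.5, 1.5), st.floats(-0.5, 0.5))
    def test_weights_sum_to_one_per_pixel(self, sigma, a1, a2):
        wf = frequency_weight(np.full((3, 3), sigma), a1, a2)
        np.testing.assert_allclose(wf.weights.sum(axis=0), 1.0, atol=1e-12)
        assert (wf.weights >= 0).all()

    def test_coefficient_decreases_with_local_contrast(self):
        sig = np.linspace(0, 10, 50)
        wf = frequency_weight(sig[None, :], a1=2 / np.pi, a2=0.0)
        # weight on the largest scale tracks A: strictly decreasing in sigma
        large = wf.weights[2, 0]
        assert (np.diff(large) < 0).all()


class TestReflectance:
    def _uniform_weights(self, shape):
        w = np.full((3,) + shape, 1.0 / 3.0)
        return WeightField(weights=w, local_sigma=np.zeros(shape), a1=0, a2=0)

    def test_constant_channel_maps_to_zero_field(self):
        kernels = [build_surround_kernel(s, 4) for s in (1.0, 2.0, 4.0)]
        c = np.full((12, 12), 0.6)
        out = msr_reflectance(c, kernels, self._uniform_weights((12, 12)), 1 / 255)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_single_scale_equals_single_scale_retinex(self, rng):
        k = build_surround_kernel(2.0, 5)
        c = rng.random((10, 10))
        w = WeightField(weights=np.ones((1, 10, 10)),
                        local_sigma=np.zeros((10, 10)), a1=0, a2=0)
        out = msr_reflectance(c, [k], w, 1 / 255)
        expected = np.log(c + 1 / 255) - np.log(estimate_incident(c, k) + 1 / 255)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        """Vectorized reflectance equals a pixel-by-pixel evaluation."""
        kernels = [build_surround_kernel(s, 3) for s in (1.0, 2.0, 3.0)]
        c = rng.random((8, 8))
        wf = self._uniform_weights((8, 8))
        out = msr_reflectance(c, kernels, wf, 1 / 255)
        incidents = [spatial_convolve_oracle(c, k.taps) for k in kernels]
        ref = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                for n in range(3):
                    ref[i, j] += wf.weights[n, i, j] * (
                        np.log(c[i, j] + 1 / 255) - np.log(incidents[n][i, j] + 1 / 255))
        np.testing.assert_allclose(out, ref, atol=1e-6)


class TestMergeAndEnhance:
    def test_achromatic_input_stays_achromatic(self, rng):
        grey = np.repeat(rng.random((10, 10, 1)), 3, axis=2)
        refl = rng.normal(size=(3, 10, 10))
        refl[1] = refl[0]
        refl[2] = refl[0]
        out = merge_and_compensate(refl, grey).pixels
        assert np.abs(out.max(axis=2) - out.min(axis=2)).max() < 1e-6

    def test_channel_ratios_preserved_at_lambda_one(self, rng):
        img = 0.1 + 0.8 * rng.random((12, 12, 3))
        refl = np.repeat(rng.normal(size=(1, 12, 12)), 3, axis=0)
        out = merge_and_compensate(refl, img, lambda_brightness=1.0).pixels
        intensity = img.mean(axis=2)
        lum = out.mean(axis=2)
        mask = (intensity > 1 / 255) & (lum > 1e-6)
        got = out[mask] / lum[mask, None]
        want = img[mask] / intensity[mask, None]
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_output_bounded_in_unit_interval(self, rng):
        out = merge_and_compensate(rng.normal(0, 10, (3, 8, 8)),
                                   rng.random((8, 8, 3))).pixels
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_enhance_is_deterministic_and_shape_preserving(self, rng):
        for shape in [(24, 31), (40, 16), (17, 17)]:
            img = rng.random(shape + (3,)).astype(np.float32)
            a = enhance(img)
            b = enhance(img)
            np.testing.assert_array_equal(a.pixels, b.pixels)
            assert a.pixels.shape == shape + (3,)

    def test_low_light_fixtures_get_brighter(self):
        """Scenes scaled to low light gain mean luminance after enhancement."""
        gains = 0
        n = 50
        for s in range(n):
            img = generate_image(LABELS[s % 6], "sunny", seed=s, image_size=(48, 48))
            low = RgbImage(img.pixels * 0.3)
            out = enhance(low)
            gains += out.pixels.mean() > low.pixels.mean()
        assert gains >= int(0.95 * n)

    def test_contrast_gain_on_degraded_fixtures(self):
        """RMS contrast rises on foggy and low-light fixtures."""
        wins = 0
        n = 50
        for s in range(n):
            cond = "foggy" if s % 2 else "cloudy"
            img = generate_image(LABELS[s % 6], cond, seed=100 + s, image_size=(48, 48))
            out = enhance(img)
            wins += out.pixels.mean(axis=2).std() >= img.pixels.mean(axis=2).std()
        assert wins >= int(0.90 * n)

    def test_hue_preserved_on_noiseless_fixture(self):
        """Per-pixel hue angle moves less than 1 degree at lambda = 1."""
        img = generate_image("huanglong", "sunny", seed=5, image_size=(48, 48))
        out = enhance(img)

        def hue(px):
            r, g, b = px[..., 0], px[..., 1], px[..., 2]
            return np.arctan2(np.sqrt(3) * (g - b), 2 * r - g - b)

        mask = img.pixels.mean(axis=2) > 0.05
        dh = np.angle(np.exp(1j * (hue(out.pixels) - hue(img.pixels))))
        assert np.degrees(np.abs(dh[mask])).max() < 1.0


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"sigmas": (80, 15, 250)},
        {"sigmas": (15, 80)},
        {"local_window": 4},
        {"local_window": 1},
        {"output_percentiles": (99, 1)},
        {"lambda_brightness": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnhancementConfig(**kwargs)
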