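import numpy as np
import pytest

from mff.colorspace import GaussianSpec, gaussian_smooth, rgb_to_cielab, rgb_to_lmn
from mff.saliency import (
    SaliencyParams,
    chrominance_saliency_map,
    color_prior,
    compute_bundle,
    frequency_prior,
    gradient_saliency_map,
    location_prior,
    scharr_gradients,
    visual_saliency_map,
)

from oracles import conv2d_replicate, gaussian_kernel2d

PARAMS = SaliencyParams()
SCHARR_X_RAW = np.array([[3.0, 0, -3.0], [10.0, 0, -10.0], [3.0, 0, -3.0]]) / 16.0


class TestFrequencyPrior:
    @pytest.mark.parametrize("bandpass", ["log-gabor", "dog"])
    def test_constant_image_has_no_bandpass_energy(self, bandpass):
        params = SaliencyParams(bandpass=bandpass)
        img = np.full((32, 32, 3), 0.6)
        sf = frequency_prior(img, params)
        assert np.allclose(sf, 0.0, atol=1e-8)

    def test_bright_square_is_salient(self):
        img = np.full((64, 64, 3), 0.1)
        img[24:40, 24:40] = 0.9
        sf = frequency_prior(img, PARAMS)
        inside = sf[24:40, 24:40].mean()
        border = np.concatenate([sf[:8].ravel(), sf[-8:].ravel()]).mean()
        assert inside > 2 * border

    def test_nonnegative(self, random_rgb):
        assert frequency_prior(random_rgb, PARAMS).min() >= 0.0


class TestColorPrior:
    def test_neutral_chrominance_scores_zero(self):
        # gray ramp: a*=b*=0 everywhere, so normalized channels are zero
        ramp = np.linspace(0.2, 0.8, 16)[None, :, None]
        img = np.broadcast_to(ramp, (16, 16, 3)).copy()
        sc = color_prior(img, PARAMS)
        assert np.allclose(sc, 0.0, atol=1e-8)

    def test_direct_substitution_at_unit_normalized_chrominance(self, random_rgb):
        sc = color_prior(random_rgb, PARAMS)
        _, a, b = rgb_to_cielab(random_rgb)
        an = (a - a.min()) / (a.max() - a.min())
        bn = (b - b.min()) / (b.max() - b.min())
        expected = 1.0 - np.exp(-(an**2 + bn**2) / 0.25**2)
        assert np.allclose(sc, expected, atol=1e-12)
        assert sc.max() < 1.0 and sc.min() >= 0.0


class TestLocationPrior:
    def test_center_pixel_is_one(self):
        sd = location_prior((11, 11), PARAMS)
        assert sd[5, 5] == pytest.approx(1.0)

    def test_flip_symmetry(self):
        sd = location_prior((21, 33), PARAMS)
        assert np.allclose(sd, sd[::-1, :], atol=1e-14)
        assert np.allclose(sd, sd[:, ::-1], atol=1e-14)

    def test_corner_value_direct_substitution(self):
        sd = location_prior((101, 101), SaliencyParams(sigma_d=114.0))
        assert sd[0, 0] == pytest.approx(np.exp(-(50**2 + 50**2) / 114.0**2), rel=1e-12)


class TestVisualSaliency:
    def test_recomposition(self, random_rgb):
        vs = visual_saliency_map(random_rgb, PARAMS)
        sf = frequency_prior(random_rgb, PARAMS)
        sc = color_prior(random_rgb, PARAMS)
        sd = location_prior(sf.shape, PARAMS)
        expected = gaussian_smooth(sf * sc * sd, PARAMS.smooth)
        assert np.allclose(vs, expected, atol=1e-10)

    def test_zero_prior_kills_map(self):
        gray = np.broadcast_to(np.linspace(0.2, 0.8, 16)[None, :, None], (16, 16, 3)).copy()
        assert np.allclose(visual_saliency_map(gray, PARAMS), 0.0, atol=1e-8)


class TestScharr:
    def test_constant_plane_zero_response(self):
        gx, gy = scharr_gradients(np.full((10, 10), 0.4))
        assert np.allclose(gx, 0.0, atol=1e-12)
        assert np.allclose(gy, 0.0, atol=1e-12)

    def test_ramp_response_matches_direct_convolution(self):
        # unit horizontal ramp: the raw kernel responds with the central
        # difference over a 2-px baseline, i.e. magnitude 2 in the interior
        ramp = np.tile(np.arange(12, dtype=float), (12, 1))
        gx, gy = scharr_gradients(ramp)
        expected = conv2d_replicate(ramp, SCHARR_X_RAW)
        assert np.allclose(gx, expected, atol=1e-12)
        assert np.allclose(np.abs(gx[2:-2, 2:-2]), 2.0, atol=1e-12)
        assert np.allclose(gy[2:-2, 2:-2], 0.0, atol=1e-12)

    def test_rotation_swaps_gradient_axes(self, rng):
        plane = rng.uniform(0, 1, (16, 16))
        gx, gy = scharr_gradients(plane)
        rx, ry = scharr_gradients(np.rot90(plane))
        # x/y kernels are transposes, so the gradient magnitude is rotation-invariant
        assert np.allclose(
            np.rot90(np.hypot(rx, ry), -1), np.hypot(gx, gy), atol=1e-12
        )


class TestMapOracles:
    """Each smoothed map against a monolithic transliteration (no reuse)."""

    def test_gradient_map_oracle(self, random_rgb):
        lum = rgb_to_lmn(random_rgb)[0]
        got = gradient_saliency_map(lum, PARAMS)
        gx = conv2d_replicate(lum, SCHARR_X_RAW)
        gy = conv2d_replicate(lum, SCHARR_X_RAW.T)
        expected = conv2d_replicate(np.sqrt(gx**2 + gy**2), gaussian_kernel2d(2.0, 7))
        assert np.allclose(got, expected, atol=1e-10)

    def test_chrominance_map_oracle(self, random_rgb):
        got = chrominance_saliency_map(random_rgb, PARAMS)
        r, g, b = random_rgb[..., 0], random_rgb[..., 1], random_rgb[..., 2]
        m = 0.30 * r + 0.04 * g - 0.35 * b
        n = 0.34 * r - 0.60 * g + 0.17 * b
        expected = conv2d_replicate(np.abs(m * n), gaussian_kernel2d(2.0, 7))
        assert np.allclose(got, expected, atol=1e-10)

    def test_achromatic_image_chrominance(self):
        v = np.broadcast_to(np.linspace(0.1, 0.9, 24)[None, :, None], (24, 24, 3)).copy()
        got = chrominance_saliency_map(v, PARAMS)
        vv = v[..., 0]
        expected = conv2d_replicate(np.abs((-0.01 * vv) * (-0.09 * vv)), gaussian_kernel2d(2.0, 7))
        assert np.allclose(got, expected, atol=1e-10)

    def test_black_image_chrominance_is_zero(self):
        assert np.allclose(chrominance_saliency_map(np.zeros((8, 8, 3)), PARAMS), 0.0)


class TestBundle:
    def test_maps_normalized_and_shaped(self, random_rgb):
        bundle = compute_bundle(random_rgb)
        for m in (bundle.vs, bundle.gm, bundle.cd):
            assert m.shape == random_rgb.shape[:2]
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_sharp_image_has_higher_gradient_saliency_than_blurred(self, small_pair):
        """Focus discriminability: the in-focus half outscores the defocused one."""
        sharp, blurred = small_pair.sources
        mask = small_pair.masks[0]
        lum1 = rgb_to_lmn(sharp)[0]
        lum2 = rgb_to_lmn(blurred)[0]
        gm1 = gradient_saliency_map(lum1, PARAMS)
        gm2 = gradient_saliency_map(lum2, PARAMS)
        assert gm1[mask].mean() > gm2[mask].mean()
        assert gm2[~mask].mean() > gm1[~mask].mean()

    def test_translation_equivariance_interior(self, rng):
        img = rng.uniform(0, 1, (48, 48, 3))
        shifted = np.roll(img, 5, axis=1)
        params = SaliencyParams(bandpass="dog")  # spatial filtering only
        lum = rgb_to_lmn(img)[0]
        lum_s = rgb_to_lmn(shifted)[0]
        gm = gradient_saliency_map(lum, params)
        gm_s = gradient_saliency_map(lum_s, params)
        assert np.allclose(gm[15:35, 15:30], gm_s[15:35, 20:35], atol=1e-10)
        cd = chrominance_saliency_map(img, params)
        cd_s = chrominance_saliency_map(shifted, params)
        assert np.allclose(cd[15:35, 15:30], cd_s[15:35, 20:35], atol=1e-10)
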