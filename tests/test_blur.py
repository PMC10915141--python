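"""Optics chain, blur distributions, Gaussian blurring and its MTF."""

import numpy as np
import pytest
from scipy import ndimage

import blurvision as bv
from blurvision.blur import (
    FWHM_PER_SIGMA,
    DefocusSample,
    gaussian_kernel_1d,
)


def brute_force_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Direct 2-D convolution oracle with symmetric (reflective) borders."""
    k1 = gaussian_kernel_1d(sigma)
    k2 = np.outer(k1, k1)
    r = (len(k1) - 1) // 2
    padded = np.pad(image, r, mode="symmetric")  # edge-inclusive reflection
    h, w = image.shape
    out = np.zeros_like(image, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(padded[i : i + 2 * r + 1, j : j + 2 * r + 1] * k2)
    return out


class TestOpticsChain:
    def test_zero_defocus_gives_zero_blur(self):
        assert bv.blur_circle_diameter_px(0.0, bv.OpticalConfig()) == 0.0

    def test_one_diopter_chain_matches_hand_computation(self):
        # 5.8 mm pupil, 1 D -> 0.0058 rad -> degrees -> px at 224 px / 54 deg
        optics = bv.OpticalConfig(5.8, 54.0, 224)
        expected = np.degrees(0.0058) * 224 / 54
        got = bv.blur_circle_diameter_px(1.0, optics)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.3785, abs=1e-4)

    @pytest.mark.parametrize("defocus", [0.25, 1.0, 2.0, 3.5])
    @pytest.mark.parametrize("pupil", [2.0, 5.8, 8.0])
    def test_linear_in_defocus_and_pupil(self, defocus, pupil):
        optics = bv.OpticalConfig(pupil, 54.0, 224)
        base = bv.blur_circle_diameter_px(1.0, bv.OpticalConfig(1.0, 54.0, 224))
        assert bv.blur_circle_diameter_px(defocus, optics) == pytest.approx(
            base * defocus * pupil, rel=1e-12
        )

    def test_fwhm_to_sigma(self):
        assert bv.fwhm_to_sigma(2.35482) == pytest.approx(1.0, abs=1e-5)
        assert bv.fwhm_to_sigma(0.0) == 0.0
        assert bv.fwhm_to_sigma(1.379) == pytest.approx(1.379 / FWHM_PER_SIGMA, rel=1e-12)
        assert bv.fwhm_to_sigma(1.379) == pytest.approx(0.58560, abs=1e-4)


class TestBlurDistributions:
    def test_weak_reference_values(self):
        d = bv.weak_blur_reference()
        assert d.sigma_levels == (0, 1, 2, 3, 4, 5)
        assert d.probabilities[0] == 0.694
        assert sum(d.probabilities) == pytest.approx(1.0, abs=1e-12)
        assert all(np.diff(d.probabilities) < 0)

    def test_strong_reference_values(self):
        d = bv.strong_blur_reference()
        assert d.sigma_levels == (0, 1, 2, 4, 8)
        assert all(p == 0.2 for p in d.probabilities)

    def test_distribution_invariants_enforced(self):
        with pytest.raises(ValueError):
            bv.BlurDistribution((0, 1), (0.5, 0.6))
        with pytest.raises(ValueError):
            bv.BlurDistribution((1, 0), (0.5, 0.5))
        with pytest.raises(ValueError):
            bv.BlurDistribution((0, 1), (-0.1, 1.1))

    def test_serialization_round_trip(self):
        d = bv.weak_blur_reference()
        assert bv.BlurDistribution.from_dict(d.to_dict()) == d

    def test_degenerate_all_clear_samples(self):
        samples = [DefocusSample(0.0, 0.5), DefocusSample(0.0, 0.5)]
        with pytest.warns(UserWarning):
            d = bv.derive_weak_blur_distribution(samples)
        assert d.sigma_levels == (0.0,)
        assert d.probabilities == (1.0,)

    def test_exponential_round_trip_recovery(self):
        # construct defocus samples whose binned sigma frequencies are an
        # exact decaying exponential; the fit must recover them to 1%
        optics = bv.OpticalConfig()
        px_per_diopter = bv.blur_circle_diameter_px(1.0, optics)
        rate = 0.9
        target = {0: 0.5}
        nz = np.exp(-rate * np.arange(1, 6))
        nz = 0.5 * nz / nz.sum()
        target.update({s: p for s, p in zip(range(1, 6), nz)})
        samples = [
            DefocusSample(s * FWHM_PER_SIGMA / px_per_diopter, w)
            for s, w in target.items()
        ]
        d = bv.derive_weak_blur_distribution(samples, optics)
        for lvl, p in zip(d.sigma_levels, d.probabilities):
            assert p == pytest.approx(target[int(lvl)], rel=0.01)


class TestSampler:
    def test_degenerate_distribution(self):
        d = bv.BlurDistribution((3.0,), (1.0,))
        draws = bv.sample_sigma(d, 0, size=50)
        assert np.all(draws == 3.0)

    def test_weak_reference_frequencies_match_published(self):
        d = bv.weak_blur_reference()
        draws = bv.sample_sigma(d, 0, size=100_000)
        assert abs((draws == 0).mean() - 0.694) < 0.005
        # every level within 3 binomial standard deviations
        for lvl, p in zip(d.sigma_levels, d.probabilities):
            sd = np.sqrt(p * (1 - p) / 100_000)
            assert abs((draws == lvl).mean() - p) <= 3 * sd + 1e-12

    def test_reproducible_under_seed(self):
        d = bv.strong_blur_reference()
        assert np.array_equal(bv.sample_sigma(d, 7, size=1000), bv.sample_sigma(d, 7, size=1000))


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        assert np.array_equal(bv.apply_gaussian_blur(img, 0.0), img)

    def test_constant_image_unchanged(self):
        img = np.full((12, 12), 0.37)
        for s in (0.5, 1, 3):
            assert np.allclose(bv.apply_gaussian_blur(img, s), img, atol=1e-12)

    @pytest.mark.parametrize("sigma", [0.6, 1.0, 2.3])
    @pytest.mark.parametrize("n", [8, 16])
    def test_matches_brute_force_convolution(self, sigma, n):
        rng = np.random.default_rng(42)
        img = rng.random((n, n))
        assert np.allclose(bv.apply_gaussian_blur(img, sigma),
                           brute_force_blur(img, sigma), atol=1e-10)

    def test_mean_preserved(self):
        rng = np.random.default_rng(3)
        img = rng.random((8, 8))
        out = bv.apply_gaussian_blur(img, 1.0)
        assert out.mean() == pytest.approx(img.mean(), abs=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            bv.apply_gaussian_blur(np.zeros((8, 8)), -1.0)


class TestMTF:
    def test_no_blur_passes_everything(self):
        assert bv.gaussian_mtf(0.0, 224, 17) == 1.0

    def test_sigma8_crossover_bracket(self):
        assert bv.gaussian_mtf(8, 224, 6) == pytest.approx(0.404, abs=1e-3)
        assert bv.gaussian_mtf(8, 224, 5) == pytest.approx(0.533, abs=1e-3)

    def test_monotone_in_frequency_and_sigma(self):
        ks = np.arange(0, 30)
        vals = bv.gaussian_mtf(4, 224, ks)
        assert np.all(np.diff(vals) < 0)
        sigmas = np.linspace(0.5, 8, 10)
        at_k6 = [bv.gaussian_mtf(s, 224, 6) for s in sigmas]
        assert np.all(np.diff(at_k6) < 0)

    @pytest.mark.parametrize("sigma", [1, 2, 4, 8])
    @pytest.mark.parametrize("k", [1, 3, 6, 10])
    def test_discrete_kernel_agrees_with_closed_form(self, sigma, k):
        closed = bv.gaussian_mtf(sigma, 224, k)
        discrete = bv.gaussian_mtf_discrete(sigma, 224, k)
        assert abs(closed - discrete) < 1e-3


class TestPeripheralBlur:
    def test_center_pixel_unblurred(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        out = bv.apply_peripheral_blur(img, bv.PeripheralBlurProfile(0.0, 8.0, 28.0))
        c = 64 // 2
        # the 0.5-px blur-stack quantization leaves the center nearly exact
        assert abs(out[c, c] - bv.apply_gaussian_blur(img, 0.25)[c, c]) < 2e-2
        assert abs(out[c, c] - img[c, c]) < 6e-2

    def test_saturated_periphery_matches_uniform_max_blur(self):
        rng = np.random.default_rng(1)
        img = rng.random((256, 256))
        profile = bv.PeripheralBlurProfile(0.0, 8.0, 112.0)
        out = bv.apply_peripheral_blur(img, profile)
        ref = bv.apply_gaussian_blur(img, 8.0)
        yy, xx = np.mgrid[0:256, 0:256]
        ecc = np.hypot(yy - 127.5, xx - 127.5)
        sel = ecc >= 113  # strictly beyond saturation
        assert np.allclose(out[sel], ref[sel], atol=1e-3)

    def test_local_contrast_nonincreasing_with_eccentricity(self):
        profile = bv.PeripheralBlurProfile(0.0, 8.0, 48.0)
        n = 128
        yy, xx = np.mgrid[0:n, 0:n]
        ecc = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2)
        edges = [0, 12, 24, 36, 48, 60]
        ring_sds = []
        for seed in range(10):
            img = np.random.default_rng(seed).random((n, n))
            out = bv.apply_peripheral_blur(img, profile)
            m = ndimage.uniform_filter(out, 9)
            m2 = ndimage.uniform_filter(out**2, 9)
            local_sd = np.sqrt(np.maximum(m2 - m**2, 0))
            ring_sds.append(
                [local_sd[(ecc >= lo) & (ecc < hi)].mean()
                 for lo, hi in zip(edges[:-1], edges[1:])]
            )
        mean_rings = np.mean(ring_sds, axis=0)
        assert np.all(np.diff(mean_rings) <= 1e-3)
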