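"""The segmentation chain: edge filter, unsharp mask, blur, threshold, and
full colony-mask recovery on synthetic ground truth."""
import numpy as np
import pytest
from scipy import ndimage as ndi

from invascreen.image import RasterImage
from invascreen.imgproc import (PipelineParams, find_edges, gaussian_blur,
                                make_colony_mask, otsu_threshold,
                                threshold_mask, unsharp_mask)
from invascreen.shape import measure_well
from invascreen.synthetic import (SyntheticColonySpec, rasterize_polygon,
                                  render_colony)


class TestFindEdges:
    def test_constant_image_zero_gradient(self):
        out = find_edges(np.full((30, 30), 7.0))
        assert np.allclose(out.pixels, 0.0)

    def test_vertical_step_response(self):
        h = 7.0
        img = np.zeros((20, 20))
        img[:, 10:] = h
        out = find_edges(img).pixels
        # Sobel 3×3 responds 4h on the two columns adjacent to the step
        assert np.allclose(out[5:15, 9], 4 * h)
        assert np.allclose(out[5:15, 10], 4 * h)
        assert np.allclose(out[5:15, :5], 0.0)
        assert np.allclose(out[5:15, 15:], 0.0)

    def test_transpose_symmetry(self, rng):
        img = rng.normal(0, 1, (40, 40))
        assert np.allclose(find_edges(img.T).pixels, find_edges(img).pixels.T)


class TestUnsharpMask:
    def test_constant_fixed_point(self):
        out = unsharp_mask(np.full((25, 25), 3.5), radius=4, weight=0.8)
        assert np.allclose(out.pixels, 3.5)

    def test_impulse_center_matches_kernel(self):
        # independent oracle: dense convolution with an explicit Gaussian
        # kernel built the same way scipy.ndimage truncates (4σ)
        r, w = 3.0, 0.6
        n = 61
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        half = int(4 * r + 0.5)
        x = np.arange(-half, half + 1)
        k1 = np.exp(-x ** 2 / (2 * r ** 2))
        k1 /= k1.sum()
        g0 = float(k1[half] ** 2)  # separable center weight
        expected = (1 - w * g0) / (1 - w)
        out = unsharp_mask(img, radius=r, weight=w)
        assert out.pixels[n // 2, n // 2] == pytest.approx(expected, rel=1e-6)

    def test_vanishing_weight_is_identity(self, rng):
        img = rng.normal(0, 1, (30, 30))
        out = unsharp_mask(img, radius=4, weight=1e-9)
        assert np.allclose(out.pixels, img, atol=1e-6)

    @pytest.mark.parametrize("weight", [1.0, 1.5])
    def test_weight_at_least_one_rejected(self, weight):
        with pytest.raises(ValueError, match="weight"):
            unsharp_mask(np.zeros((5, 5)), radius=4, weight=weight)


class TestGaussianBlur:
    def test_constant_unchanged(self):
        out = gaussian_blur(np.full((20, 20), 2.0), sigma=4)
        assert np.allclose(out.pixels, 2.0)

    def test_impulse_mass_conserved(self):
        img = np.zeros((101, 101))
        img[50, 50] = 1.0
        out = gaussian_blur(img, sigma=4)
        assert out.pixels.sum() == pytest.approx(1.0, rel=1e-3)

    def test_impulse_profile_matches_closed_form(self):
        sigma = 5.0
        img = np.zeros((121, 121))
        img[60, 60] = 1.0
        out = gaussian_blur(img, sigma=sigma).pixels
        for d in (3, 6, 9):
            expected = np.exp(-d ** 2 / (2 * sigma ** 2))
            assert out[60, 60 + d] / out[60, 60] == pytest.approx(expected, rel=0.02)


class TestThreshold:
    def test_two_valued_image_separates(self):
        img = np.full((50, 50), 10.0)
        img.ravel()[:1000] = 200.0
        thr = otsu_threshold(img)
        assert 10 < thr < 200
        mask = threshold_mask(img, PipelineParams(fill_holes=False))
        assert np.array_equal(mask.pixels, img > thr)

    def test_otsu_equals_bruteforce(self, rng):
        img = np.concatenate([rng.normal(40, 8, 2000), rng.normal(150, 20, 1200)])
        img = img.reshape(40, 80)
        # brute force over all 256 histogram cut points
        hist, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best, best_var = None, -1.0
        for i in range(1, 256):
            w0, w1 = hist[:i].sum(), hist[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:i] * centers[:i]).sum() / w0
            m1 = (hist[i:] * centers[i:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best_var, best = var, centers[i - 1:i + 1].mean()
        assert otsu_threshold(img) == pytest.approx(best, abs=(edges[1] - edges[0]))

    def test_manual_extremes(self):
        img = np.linspace(10, 240, 100).reshape(10, 10)
        low = threshold_mask(img, PipelineParams(threshold_method="manual",
                                                 manual_threshold=5))
        high = threshold_mask(img, PipelineParams(threshold_method="manual",
                                                  manual_threshold=250))
        assert low.pixels.all() and not high.pixels.any()

    def test_constant_image_needs_manual(self):
        with pytest.raises(ValueError, match="manual"):
            threshold_mask(np.full((10, 10), 3.0))

    def test_manual_requires_value(self):
        with pytest.raises(ValueError, match="manual_threshold"):
            PipelineParams(threshold_method="manual")


class TestColonyMask:
    def test_single_disc_recovered(self):
        spec = SyntheticColonySpec(center=(128, 128), base_radius=80, seed=1)
        img, poly = render_colony(spec, (256, 256), noise_level=0.02)
        mask = make_colony_mask(img)
        assert len(measure_well(mask)) == 1
        truth = rasterize_polygon(poly, (256, 256))
        jac = (mask.pixels & truth).sum() / (mask.pixels | truth).sum()
        assert jac >= 0.9

    def test_blank_noise_yields_nothing(self, rng):
        img = 0.8 + rng.normal(0, 0.02, (256, 256))
        mask = make_colony_mask(img)
        assert not mask.pixels.any()

    def test_deterministic(self):
        spec = SyntheticColonySpec(center=(128, 128), base_radius=60,
                                   n_spikes=5, spike_amplitude=0.3, seed=9)
        img, _ = render_colony(spec, (256, 256))
        m1 = make_colony_mask(img)
        m2 = make_colony_mask(img)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_shift_equivariance_interior(self, rng):
        base = rng.normal(0, 1, (80, 80))
        big = np.zeros((120, 120))
        big[10:90, 10:90] = base
        shifted = np.zeros((120, 120))
        shifted[15:95, 17:97] = base
        a = find_edges(big).pixels
        a = unsharp_mask(a, 4, 0.8).pixels
        a = gaussian_blur(a, 4).pixels
        b = find_edges(shifted).pixels
        b = unsharp_mask(b, 4, 0.8).pixels
        b = gaussian_blur(b, 4).pixels
        # compare a deep interior crop of the colony region
        assert np.allclose(a[40:60, 40:60], b[45:65, 47:67], atol=1e-8)

    def test_mask_recovery_over_random_colonies(self):
        # ≥95% of random colonies recovered with Jaccard ≥ 0.85 at default noise
        rng = np.random.default_rng(11)
        good = total = 0
        for _ in range(50):
            spec = SyntheticColonySpec(
                center=(160, 160),
                base_radius=float(rng.uniform(50, 80)),
                n_spikes=int(rng.integers(3, 10)),
                spike_amplitude=float(rng.uniform(0, 0.45)),
                radial_jitter=0.03,
                seed=int(rng.integers(0, 2 ** 31)))
            img, poly = render_colony(spec, (320, 320), noise_level=0.02)
            mask = make_colony_mask(img)
            truth = rasterize_polygon(poly, (320, 320))
            union = (mask.pixels | truth).sum()
            jac = (mask.pixels & truth).sum() / union if union else 0.0
            total += 1
            good += jac >= 0.85
        assert good / total >= 0.95


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        dict(unsharp_radius=0), dict(unsharp_weight=1.2),
        dict(gaussian_sigma=-1), dict(min_area=-5), dict(pixel_size=0),
        dict(threshold_method="magic")])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            PipelineParams(**kw)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            RasterImage(np.zeros((0, 4)))
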