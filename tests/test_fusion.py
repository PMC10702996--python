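"""Fusion preprocessing: brightness transform, exposure search, mean filter,
multi-scale morphological gradient, and focus-driven blending."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.morphology import disk

from pdfuse import fusion
from pdfuse.fusion import FusionConfig


@pytest.fixture()
def cfg():
    return FusionConfig()


class TestBTF:
    def test_identity_at_k_equal_one(self, cfg, rng):
        img = rng.random((16, 16))
        assert np.allclose(fusion.btf(img, 1.0, cfg), img, atol=1e-12)

    def test_zero_pixel_stays_zero(self, cfg):
        img = np.zeros((4, 4))
        assert np.all(fusion.btf(img, 3.7, cfg) == 0.0)

    def test_matches_scalar_closed_form(self):
        cfg = FusionConfig(btf_a=0.3293, btf_b=1.158)
        a, b, k, p = 0.3293, 1.158, 2.0, 0.5
        expected = np.exp(b * (1 - k**a)) * p ** (k**a)
        got = fusion.btf(np.full((2, 2), p), k, cfg)
        assert np.allclose(got, expected, atol=1e-14)

    def test_invalid_k_and_nan_rejected(self, cfg):
        with pytest.raises(ValueError, match="k"):
            fusion.btf(np.zeros((2, 2)), 0.0, cfg)
        with pytest.raises(ValueError, match="NaN"):
            fusion.btf(np.array([[np.nan, 0.0]]), 2.0, cfg)


class TestIlluminationWeight:
    def test_constant_extremes(self, cfg):
        assert np.allclose(fusion.illumination_weight(np.ones((8, 8)), cfg), 1.0)
        assert np.allclose(fusion.illumination_weight(np.zeros((8, 8)), cfg), 0.0)

    def test_half_dark_half_bright_monotone_across_boundary(self, cfg):
        img = np.zeros((32, 64))
        img[:, 32:] = 1.0
        W = fusion.illumination_weight(img, cfg)
        row = W[16]
        assert row[0] < 0.2 and row[-1] > 0.8
        assert np.all(np.diff(row) >= -1e-12)  # monotone along the row
        # Oracle: smoothed luminance ** mu with the same kernel.
        expected = np.clip(gaussian_filter(img, 5.0, mode="reflect"), 0, 1) ** 0.5
        assert np.allclose(W, expected, atol=1e-12)


class TestExposureRatio:
    def test_no_underexposed_pixel_returns_one(self, cfg):
        img = np.full((16, 16), 0.9)
        W = np.ones_like(img)
        assert fusion.find_exposure_ratio(img, W, cfg) == 1.0

    def test_constant_dark_image_ties_to_lower_bound(self, cfg):
        img = np.full((16, 16), 0.05)
        W = np.zeros_like(img)
        assert fusion.find_exposure_ratio(img, W, cfg) == cfg.k_search_range[0]

    def test_two_level_image_matches_fine_grid_scan(self, cfg):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((32, 32)) < 0.5, 0.05, 0.15)
        W = np.zeros_like(img)
        k = fusion.find_exposure_ratio(img, W, cfg)
        # Brute force at step 1e-4, ties toward smallest k.
        Q = img.ravel()
        ks = np.arange(*cfg.k_search_range, 1e-4)
        ents = []
        for kk in ks:
            g = fusion.btf(Q, kk, cfg)
            hist, _ = np.histogram(g, bins=cfg.entropy_bins, range=(0, 1))
            p = hist[hist > 0] / Q.size
            ents.append(-(p * np.log2(p)).sum())
        ents = np.array(ents)
        k_brute = ks[np.flatnonzero(ents >= ents.max() - 1e-12)[0]]
        assert abs(k - k_brute) <= 0.01


class TestEnhance:
    def test_constant_bright_image_unchanged(self, cfg):
        img = np.ones((16, 16))
        res = fusion.enhance(img, cfg)
        assert np.allclose(res.enhanced, 1.0)

    def test_reconstruction_identity(self, cfg, rng):
        img = rng.random((32, 32))
        res = fusion.enhance(img, cfg)
        recon = res.weight_map * img + (1 - res.weight_map) * res.synthetic_exposure
        assert np.max(np.abs(res.enhanced - recon)) < 1e-10

    def test_mean_not_darkened_on_default_phantom(self, cfg):
        from pdfuse import phantoms
        img = phantoms.generate_phantom(phantoms.PhantomSpec(seed=7))
        res = fusion.enhance(img, cfg)
        assert res.enhanced.mean() >= img.mean() - 1e-12


class TestMeanFilter:
    def test_constant_preserved(self):
        img = np.full((8, 8), 0.37)
        assert np.allclose(fusion.mean_filter(img, 3), 0.37)

    def test_unit_impulse_spreads_to_box(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = fusion.mean_filter(img, 3)
        assert np.allclose(out[3:6, 3:6], 1 / 9)
        assert np.allclose(out[np.abs(np.arange(9) - 4) > 1], 0.0)

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_naive_double_loop(self, window, rng):
        img = rng.random((16, 16))
        r = window // 2
        pad = np.pad(img, r, mode="symmetric")
        naive = np.empty_like(img)
        for i in range(16):
            for j in range(16):
                naive[i, j] = pad[i:i + window, j:j + window].mean()
        assert np.max(np.abs(fusion.mean_filter(img, window) - naive)) < 1e-12

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            fusion.mean_filter(np.zeros((4, 4)), 4)


def naive_msmg(img: np.ndarray, n_scales: int, base_radius: int = 1) -> np.ndarray:
    """Per-scale loop oracle with explicit max/min over the footprint."""
    base = disk(base_radius).astype(bool)
    se = base
    M = np.zeros_like(img)
    H, W = img.shape
    for t in range(1, n_scales + 1):
        r = se.shape[0] // 2
        pad = np.pad(img, r, mode="symmetric")
        offs = [(i, j) for i in range(se.shape[0]) for j in range(se.shape[1])
                if se[i, j]]
        dil = np.empty_like(img)
        ero = np.empty_like(img)
        for i in range(H):
            for j in range(W):
                vals = [pad[i + di, j + dj] for di, dj in offs]
                dil[i, j] = max(vals)
                ero[i, j] = min(vals)
        M += (dil - ero) / (2 * t + 1)
        se = binary_dilation(se, structure=base)
    return M


class TestMSMG:
    def test_constant_image_zero_gradient(self, cfg):
        assert np.allclose(fusion.msmg(np.full((16, 16), 0.5), cfg).values, 0.0)

    def test_weight_sequence(self):
        assert np.allclose(fusion.msmg_weights(3), [1 / 3, 1 / 5, 1 / 7])

    def test_matches_naive_loop(self, cfg, rng):
        img = rng.random((16, 16))
        got = fusion.msmg(img, cfg).values
        assert np.max(np.abs(got - naive_msmg(img, cfg.msmg_scales))) < 1e-12

    def test_step_edge_single_scale(self):
        cfg1 = FusionConfig(msmg_scales=1)
        img = np.zeros((12, 12))
        img[:, 6:] = 0.8
        M = fusion.msmg(img, cfg1).values
        # Nonzero only within one SE radius of the edge, magnitude h*w1.
        assert np.allclose(M[:, 5:7], 0.8 / 3)
        assert np.allclose(M[:, :5], 0.0) and np.allclose(M[:, 7:], 0.0)

    def test_nonnegative(self, cfg, rng):
        assert fusion.msmg(rng.random((20, 20)), cfg).values.min() >= 0.0


class TestFuse:
    def test_identical_inputs_any_mode(self, rng):
        img = rng.random((16, 16))
        for mode in ("soft", "hard"):
            out = fusion.fuse(img, img, FusionConfig(blend_mode=mode))
            assert np.allclose(out, img, atol=1e-12)

    def test_hard_mode_selects_stronger_gradient(self, rng):
        textured = gaussian_filter(rng.random((24, 24)), 0.8)
        flat = np.full((24, 24), textured.mean())
        out = fusion.fuse(textured, flat, FusionConfig(blend_mode="hard"))
        assert np.allclose(out, textured)

    def test_split_focus_composite_recovery(self, rng):
        sharp = gaussian_filter(rng.random((64, 64)), 1.0)
        blur = gaussian_filter(sharp, 3.0)
        left_sharp = sharp.copy(); left_sharp[:, 32:] = blur[:, 32:]
        right_sharp = sharp.copy(); right_sharp[:, :32] = blur[:, :32]
        out = fusion.fuse(left_sharp, right_sharp, FusionConfig(blend_mode="hard"))
        inner = (slice(4, 60), slice(4, 60))
        agreement = np.mean(np.abs(out[inner] - sharp[inner]) <= 1e-3)
        assert agreement >= 0.95

    def test_soft_mode_symmetric_under_swap(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        cfg = FusionConfig(blend_mode="soft")
        assert np.allclose(fusion.fuse(a, b, cfg), fusion.fuse(b, a, cfg), atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            fusion.fuse(np.zeros((4, 4)), np.zeros((5, 5)))


def test_all_stage_outputs_stay_in_unit_interval(rng):
    img = rng.random((32, 32))
    cfg = FusionConfig()
    res = fusion.enhance(img, cfg)
    fused, _ = fusion.preprocess_image(img, cfg)
    for arr in (res.enhanced, res.weight_map, res.synthetic_exposure,
                fusion.mean_filter(img, 3), fused):
        assert np.isfinite(arr).all()
        assert arr.min() >= 0.0 and arr.max() <= 1.0
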