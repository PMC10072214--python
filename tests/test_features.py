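"""First-order, shape and filter-bank features against small oracles."""

import numpy as np
import pytest
import pywt

from radsurv.features import (
    FIRST_ORDER_NAMES,
    SHAPE_NAMES,
    DiscretizationSpec,
    FilterBank,
    apply_log,
    apply_wavelet,
    compute_first_order,
    compute_shape,
    extract_all,
    feature_names,
)
from radsurv.volume import ImageVolume, VOIMask

DISC = DiscretizationSpec(bin_width=1.0)


def _vol_mask(values, mask=None, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return ImageVolume(values, spacing), VOIMask(mask, spacing)


class TestFirstOrder:
    def test_constant_region_degenerate_conventions(self):
        vol, mask = _vol_mask(np.full((3, 3, 3), 7.0))
        f = compute_first_order(vol, mask, DISC)
        assert f["Mean"] == 7.0
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0

    def test_hand_arithmetic_fixture(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        vol, mask = _vol_mask(vals)
        f = compute_first_order(vol, mask, DISC)
        assert f["Mean"] == 2.5
        assert f["Energy"] == 30.0
        assert f["Range"] == 3.0
        assert f["Median"] == 2.5
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))

    def test_count_is_18_and_matches_direct_moments(self):
        rng = np.random.default_rng(0)
        vol, mask = _vol_mask(rng.normal(50, 20, (6, 6, 6)), rng.uniform(size=(6, 6, 6)) < 0.7)
        f = compute_first_order(vol, mask, DISC)
        assert len(f) == 18 and set(f) == set(FIRST_ORDER_NAMES)
        x = vol.values[mask.values]
        assert f["Mean"] == pytest.approx(x.mean(), abs=1e-12)
        assert f["Variance"] == pytest.approx(x.var(), abs=1e-12)

    def test_empty_mask_raises(self):
        vol, _ = _vol_mask(np.zeros((3, 3, 3)))
        empty = VOIMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="empty mask"):
            compute_first_order(vol, empty, DISC)


class TestShape:
    def test_ball_volume_and_sphericity(self, ball_mask):
        f = compute_shape(ball_mask)
        assert f["VoxelVolume"] == pytest.approx(4188.79, rel=0.05)
        assert 0.95 < f["Sphericity"] <= 1.0
        assert f["Maximum3DDiameter"] == pytest.approx(20.0, rel=0.1)

    def test_cube_is_isotropic(self):
        arr = np.zeros((12, 12, 12), bool)
        arr[3:9, 3:9, 3:9] = True
        f = compute_shape(VOIMask(arr, (1.0, 1.0, 1.0)))
        assert f["Elongation"] == pytest.approx(1.0)
        assert f["Flatness"] == pytest.approx(1.0)

    def test_count_is_14(self, ball_mask):
        f = compute_shape(ball_mask)
        assert len(f) == 14 and set(f) == set(SHAPE_NAMES)

    def test_single_voxel_fallback(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[2, 2, 2] = True
        f = compute_shape(VOIMask(arr, (1.0, 1.0, 1.0)))
        assert f["MajorAxisLength"] == 0.0
        assert f["VoxelVolume"] == 1.0
        assert f["MeshVolume"] > 0

    def test_anisotropic_spacing_scales_volume(self):
        arr = np.zeros((8, 8, 8), bool)
        arr[2:6, 2:6, 2:6] = True
        f1 = compute_shape(VOIMask(arr, (1.0, 1.0, 1.0)))
        f2 = compute_shape(VOIMask(arr, (2.0, 1.0, 1.0)))
        assert f2["VoxelVolume"] == pytest.approx(2 * f1["VoxelVolume"])


class TestLoG:
    def test_constant_volume_zero_response(self):
        vol = ImageVolume(np.full((16, 16, 16), 100.0), (1, 1, 1))
        out = apply_log(vol, 2.0)
        assert np.abs(out.values).max() < 1e-6

    def test_impulse_matches_analytic_kernel(self):
        n = 33
        arr = np.zeros((n, n, n))
        arr[n // 2, n // 2, n // 2] = 1.0
        sigma = 2.0
        out = apply_log(ImageVolume(arr, (1, 1, 1)), sigma).values
        g = np.arange(n) - n // 2
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        r2 = xx**2 + yy**2 + zz**2
        gauss = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2) ** 1.5
        analytic = gauss * (r2 - 3 * sigma**2) / sigma**4
        # residual is the sum-normalization of the sampled Gaussian kernel
        assert np.abs(out - analytic).max() < 5e-6

    def test_linearity(self):
        rng = np.random.default_rng(1)
        vol = ImageVolume(rng.normal(size=(12, 12, 12)), (1, 1, 1))
        a = apply_log(vol.with_values(3.0 * vol.values), 1.5).values
        b = 3.0 * apply_log(vol, 1.5).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_spacing_awareness(self):
        """Physically identical inputs give identical responses."""
        rng = np.random.default_rng(2)
        coarse = rng.normal(size=(16, 16, 16))
        v1 = apply_log(ImageVolume(coarse, (2.0, 2.0, 2.0)), 4.0).values
        v2 = apply_log(ImageVolume(coarse, (1.0, 1.0, 1.0)), 2.0).values
        np.testing.assert_allclose(v1, v2, atol=1e-12)


class TestWavelet:
    def test_eight_labeled_subbands(self):
        vol = ImageVolume(np.random.default_rng(0).normal(size=(20, 20, 20)), (1, 1, 1))
        bands = apply_wavelet(vol, FilterBank())
        assert set(bands) == {"LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"}
        assert all(b.shape == vol.shape for b in bands.values())

    def test_highpass_of_constant_is_zero(self):
        vol = ImageVolume(np.full((20, 20, 20), 5.0), (1, 1, 1))
        bands = apply_wavelet(vol, FilterBank())
        assert np.abs(bands["HHH"].values).max() < 1e-9

    def test_lowpass_of_constant_scales_by_coefficient_sum_cubed(self):
        c = 5.0
        vol = ImageVolume(np.full((20, 20, 20), c), (1, 1, 1))
        bands = apply_wavelet(vol, FilterBank())
        scale = sum(pywt.Wavelet("bior6.8").dec_lo) ** 3
        np.testing.assert_allclose(bands["LLL"].values, c * scale, rtol=1e-10)

    def test_grid_too_small_raises(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError, match="at least"):
            apply_wavelet(vol, FilterBank())


@pytest.fixture(scope="module")
def textured():
    rng = np.random.default_rng(4)
    vals = rng.normal(60, 30, (20, 20, 20))
    mask = np.zeros((20, 20, 20), bool)
    mask[6:14, 6:14, 6:14] = True
    return ImageVolume(vals, (1, 1, 1)), VOIMask(mask, (1, 1, 1))


class TestExtractAll:

    def test_default_bank_feature_counts(self, textured):
        vol, mask = textured
        feats = extract_all(vol, mask, DiscretizationSpec(bin_width=25.0), FilterBank())
        assert len(feats) == 107 + 13 * 93  # = 1316, incl. 1209 derived
        derived = [k for k in feats if not k.startswith("original_")]
        assert len(derived) == 1209
        assert list(feats) == feature_names(FilterBank())

    def test_empty_bank_gives_base_107(self, textured):
        vol, mask = textured
        feats = extract_all(vol, mask, DiscretizationSpec(bin_width=25.0), None)
        assert len(feats) == 107

    def test_shape_subvector_is_mask_only(self, textured):
        vol, mask = textured
        other = vol.with_values(vol.values * 0.1 + 7.0)  # stand-in dose map
        a = extract_all(vol, mask, DiscretizationSpec(bin_width=25.0), None)
        b = extract_all(other, mask, DiscretizationSpec(bin_width=0.5), None)
        for name in SHAPE_NAMES:
            assert a[f"original_shape_{name}"] == b[f"original_shape_{name}"]

    def test_background_relabeling_invariance(self, textured):
        """Features ignore voxels outside the mask entirely."""
        vol, mask = textured
        scrambled = vol.values.copy()
        scrambled[~mask.values] = 9999.0
        a = extract_all(vol, mask, DiscretizationSpec(bin_width=25.0), None)
        b = extract_all(vol.with_values(scrambled), mask, DiscretizationSpec(bin_width=25.0), None)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)
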