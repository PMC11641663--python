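"""Radiomics engine: Dice, filters, discretization, feature formulas."""

import numpy as np
import pytest

from conftest import full_mask, make_volume, random_roi
from oracles import texture_oracle
from radgenmap.radiomics import (
    BinaryMask,
    DiscretizedROI,
    FilterSpec,
    ImageVolume,
    apply_filter,
    dice,
    discretize,
    extract_feature_vector,
    firstorder_features,
    texture_features,
)


class TestDice:
    def test_identical_nonempty_masks_give_one(self):
        m = BinaryMask((np.arange(27).reshape(3, 3, 3) % 2).astype(np.uint8))
        assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((3, 3, 3), dtype=np.uint8)
        b = np.zeros((3, 3, 3), dtype=np.uint8)
        a[0] = 1
        b[2] = 1
        assert dice(BinaryMask(a), BinaryMask(b)) == 0.0

    def test_half_overlap(self):
        # |A|=4, |B|=4, |A n B|=2 -> 2*2/8 = 0.5
        a = np.zeros((2, 2, 2), dtype=np.uint8)
        b = np.zeros((2, 2, 2), dtype=np.uint8)
        a.flat[:4] = 1
        b.flat[2:6] = 1
        assert dice(BinaryMask(a), BinaryMask(b)) == 0.5

    def test_symmetry_and_range(self, rng):
        a = BinaryMask((rng.random((4, 4, 4)) < 0.5).astype(np.uint8))
        b = BinaryMask((rng.random((4, 4, 4)) < 0.5).astype(np.uint8))
        d1, d2 = dice(a, b), dice(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0

    def test_errors(self):
        empty = BinaryMask(np.zeros((2, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            dice(empty, empty)
        with pytest.raises(ValueError):
            dice(full_mask((2, 2, 2)), full_mask((3, 3, 3)))


class TestFilters:
    def test_log_of_constant_is_zero(self):
        v = make_volume(np.full((8, 8, 8), 5.0))
        out = apply_filter(v, FilterSpec("log_sigma", sigma_mm=2.0))
        assert np.allclose(out.grid, 0.0, atol=1e-10)

    def test_wavelet_lll_of_constant_is_constant(self):
        v = make_volume(np.full((8, 8, 8), 7.0))
        out = apply_filter(v, FilterSpec("wavelet", subband="LLL"))
        assert np.allclose(out.grid, 7.0, atol=1e-10)

    def test_wavelet_high_pass_of_constant_is_zero(self):
        v = make_volume(np.full((8, 8, 8), 7.0))
        out = apply_filter(v, FilterSpec("wavelet", subband="LLH"))
        assert np.allclose(out.grid, 0.0, atol=1e-10)

    def test_logarithm_of_constant_is_constant(self):
        v = make_volume(np.full((6, 6, 6), 9.0))
        out = apply_filter(v, FilterSpec("logarithm"))
        assert np.allclose(out.grid, out.grid.flat[0])

    def test_shape_and_spacing_preserved(self, rng):
        v = make_volume(rng.normal(size=(7, 6, 5)), spacing=(1.0, 0.5, 2.0))
        for spec in (
            FilterSpec("original"),
            FilterSpec("log_sigma", sigma_mm=3.0),
            FilterSpec("wavelet", subband="HLH"),
            FilterSpec("logarithm"),
            FilterSpec("lbp3d"),
        ):
            out = apply_filter(v, spec)
            assert out.grid.shape == v.grid.shape
            assert out.spacing_mm == v.spacing_mm

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("gradient")
        with pytest.raises(ValueError):
            FilterSpec("wavelet", subband="LLX")
        with pytest.raises(ValueError):
            FilterSpec("log_sigma")
        with pytest.raises(ValueError):
            FilterSpec("original", sigma_mm=2.0)


class TestDiscretize:
    def test_floor_rule(self):
        v = make_volume(np.array([0.0, 19.0, 20.0]).reshape(1, 1, 3))
        d = discretize(v, full_mask((1, 1, 3)), bin_width=20)
        assert list(d.levels_flat) == [1, 1, 2]

    def test_constant_roi_single_level(self):
        v = make_volume(np.full((2, 2, 2), 3.0))
        d = discretize(v, full_mask((2, 2, 2)), bin_width=20)
        assert d.ng == 1
        assert set(d.levels_flat) == {1}

    def test_range_99_gives_five_levels(self):
        v = make_volume(np.linspace(0, 99, 8).reshape(2, 2, 2))
        d = discretize(v, full_mask((2, 2, 2)), bin_width=20)
        assert d.ng == 5

    def test_invalid_bin_width(self):
        v = make_volume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            discretize(v, full_mask((2, 2, 2)), bin_width=0)


class TestFirstOrder:
    def test_symmetric_values_have_zero_skewness(self):
        f = firstorder_features(np.array([1.0, 2.0, 3.0]))
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_roi_minimum_and_skew_convention(self):
        f = firstorder_features(np.full(5, 7.0))
        assert f["Minimum"] == 7.0
        assert f["Skewness"] == 0.0

    def test_skewness_matches_third_standardized_moment(self):
        x = np.array([1.0, 1.0, 1.0, 10.0])
        mu = x.mean()
        expected = np.mean((x - mu) ** 3) / np.mean((x - mu) ** 2) ** 1.5
        assert firstorder_features(x)["Skewness"] == pytest.approx(expected, rel=1e-12)

    def test_shift_invariance_of_skewness_minimum_equivariance(self, rng):
        x = rng.normal(size=50)
        f0 = firstorder_features(x)
        f1 = firstorder_features(x + 100.0)
        assert f1["Skewness"] == pytest.approx(f0["Skewness"], abs=1e-9)
        assert f1["Minimum"] == pytest.approx(f0["Minimum"] + 100.0)


class TestTextureTrivial:
    def test_constant_roi_imc2_zero(self):
        d = DiscretizedROI(np.ones((3, 3, 3), dtype=np.int64), np.ones((3, 3, 3), bool), 1.0)
        assert texture_features(d, "GLCM")["Imc2"] == pytest.approx(0.0, abs=1e-12)

    def test_single_voxel_glrlm_lowgraylevel_is_one(self):
        grid = np.zeros((3, 3, 3), dtype=np.int64)
        mask = np.zeros((3, 3, 3), bool)
        grid[1, 1, 1] = 1
        mask[1, 1, 1] = True
        d = DiscretizedROI(grid, mask, 1.0)
        assert texture_features(d, "GLRLM")["LowGrayLevelRunEmphasis"] == pytest.approx(1.0)

    def test_unknown_family_rejected(self, toy_roi):
        with pytest.raises(ValueError):
            texture_features(toy_roi, "NGTDM")


@pytest.mark.parametrize("family", ["GLCM", "GLRLM", "GLSZM", "GLDM"])
class TestTextureOracle:
    def test_toy_grid_matches_enumeration(self, toy_roi, family):
        """The fixed 4x4x1 grid: every family equals the exhaustive
        enumeration oracle."""
        got = texture_features(toy_roi, family)
        want = texture_oracle(toy_roi.level_grid, toy_roi.mask, family)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_random_rois_match_enumeration(self, rng, family):
        """Random ROIs up to 6x6x6 with Ng <= 4 match the brute-force
        oracle to 1e-10."""
        for _ in range(12):
            d = random_roi(rng)
            got = texture_features(d, family)
            want = texture_oracle(d.level_grid, d.mask, family)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-10), k


class TestMatrixInvariants:
    def test_probability_forms_normalized(self, rng):
        from radgenmap.radiomics import glcm_matrices, gldm_matrix, glszm_matrix

        for _ in range(5):
            d = random_roi(rng)
            for m in glcm_matrices(d):
                assert (m >= 0).all()
                if m.sum() > 0:
                    assert (m / m.sum()).sum() == pytest.approx(1.0)
            for m in (glszm_matrix(d), gldm_matrix(d)):
                assert (m >= 0).all()
                assert (m / m.sum()).sum() == pytest.approx(1.0)


class TestFeatureVector:
    def test_deterministic_and_named(self, rng):
        v = make_volume(rng.normal(50, 20, (10, 10, 10)))
        m = full_mask((10, 10, 10))
        f1 = extract_feature_vector(v, m)
        f2 = extract_feature_vector(v, m)
        assert f1 == f2
        assert "wavelet-LHL_glszm_SmallAreaLowGrayLevelEmphasis" in f1
        assert "log-sigma-2mm_firstorder_Skewness" in f1

    def test_intensity_shift_changes_minimum_not_skewness(self, rng):
        grid = rng.normal(50, 20, (8, 8, 8))
        m = full_mask((8, 8, 8))
        filters = (FilterSpec("original"),)
        f0 = extract_feature_vector(make_volume(grid), m, filters)
        f1 = extract_feature_vector(make_volume(grid + 100.0), m, filters)
        assert f1["original_firstorder_Minimum"] == pytest.approx(
            f0["original_firstorder_Minimum"] + 100.0
        )
        assert f1["original_firstorder_Skewness"] == pytest.approx(
            f0["original_firstorder_Skewness"], abs=1e-9
        )

    def test_empty_mask_rejected(self, rng):
        v = make_volume(rng.normal(size=(8, 8, 8)))
        with pytest.raises(ValueError):
            extract_feature_vector(v, BinaryMask(np.zeros((8, 8, 8), dtype=np.uint8)))
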