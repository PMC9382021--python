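import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from habitomics.features.filters import (
    apply_filter,
    lbp3d_maps,
    log_filter,
    square_filter,
    squareroot_filter,
    wavelet_bands,
)
from habitomics.features.firstorder import firstorder_features
from habitomics.features.texture import (
    DiscretizationSettings,
    discretize,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from habitomics.features.extract import FeatureConfig, extract_all

from oracles import oracle_glcm, oracle_glrlm, oracle_glszm, oracle_ngtdm

DIRS_2D = [(0, 1, 0), (1, 0, 0), (1, 1, 0), (1, -1, 0)]
DIRS_3D = [
    d
    for d in [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)]
    if d != (0, 0, 0) and next(x for x in d if x != 0) > 0
]


def random_level_image(rng, shape, n_levels=4, mask_p=0.75):
    levels = rng.integers(1, n_levels + 1, shape)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask.flat[0] = True
    return levels * mask, mask


class TestFilters:
    def test_wavelet_high_pass_kills_constants(self):
        bands = wavelet_bands(np.full((10, 10, 6), 3.5))
        for name, band in bands.items():
            if "H" in name:
                assert np.allclose(band, 0.0, atol=1e-12)
        assert set(bands) == {
            "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
        }

    def test_wavelet_bands_keep_input_shape_odd_dims(self):
        bands = wavelet_bands(np.random.default_rng(0).random((9, 11, 5)))
        assert all(b.shape == (9, 11, 5) for b in bands.values())

    def test_log_of_constant_is_zero(self):
        out = log_filter(np.full((20, 20, 8), 5.0), sigma_mm=2.0, spacing_mm=(1, 1, 1))
        assert np.abs(out).max() < 1e-10

    def test_square_preserves_order_and_max_on_nonnegative(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 6, 4)) * 50
        out = square_filter(x)
        assert np.isclose(out.max(), x.max())
        assert np.array_equal(np.argsort(out.ravel()), np.argsort(x.ravel()))

    def test_squareroot_signed_and_rescaled(self):
        x = np.array([[[-4.0, 0.0, 9.0]]])
        out = squareroot_filter(x)
        assert out[0, 0, 1] == 0.0
        assert out[0, 0, 0] < 0 < out[0, 0, 2]
        assert np.isclose(np.abs(out).max(), 9.0)

    def test_lbp_maps_deterministic_and_shaped(self):
        rng = np.random.default_rng(2)
        x = rng.random((7, 7, 4))
        a = lbp3d_maps(x)
        b = lbp3d_maps(x)
        assert set(a) == {"m1", "m2", "k"}
        for key in a:
            assert a[key].shape == x.shape
            assert np.array_equal(a[key], b[key])

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_filter(np.zeros((4, 4, 4)), (1, 1, 1), "gabor")


class TestFirstorder:
    def test_hand_worked_values(self):
        f = firstorder_features(np.array([3.0, 4.0]))
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(12.5))
        f = firstorder_features(np.arange(1.0, 11.0))
        assert f["10Percentile"] == pytest.approx(1.9)
        assert f["InterquartileRange"] == pytest.approx(7.75 - 3.25)

    def test_symmetric_sample_has_zero_skewness(self):
        f = firstorder_features(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample_skewness_zero_by_convention(self):
        assert firstorder_features(np.full(5, 2.0))["Skewness"] == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40), st.randoms())
    def test_permutation_invariance(self, values, rnd):
        x = np.array(values)
        perm = x.copy()
        rnd.shuffle(perm)
        a = firstorder_features(x)
        b = firstorder_features(perm)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9)


class TestTextureExamples:
    def test_glcm_1x3_single_direction(self):
        vals = glcm_features(np.array([[1, 2, 1]]), np.ones((1, 3)), directions=[(0, 1, 0)])
        assert vals["InverseVariance"] == pytest.approx(1.0)

    def test_glcm_constant_imc1_zero(self):
        vals = glcm_features(
            np.full((4, 4), 7.0), np.ones((4, 4)), DiscretizationSettings()
        )
        assert vals["Imc1"] == 0.0

    def test_glrlm_row_example(self):
        vals = glrlm_features(np.array([[1, 1, 2]]), np.ones((1, 3)), directions=[(0, 1, 0)])
        assert vals["LongRunEmphasis"] == pytest.approx(2.5)

    def test_glrlm_constant_row(self):
        vals = glrlm_features(
            np.ones((1, 7), dtype=int), np.ones((1, 7)), directions=[(0, 1, 0)]
        )
        assert vals["LongRunEmphasis"] == pytest.approx(49.0)

    def test_glszm_2x2_example(self):
        vals = glszm_features(np.array([[1, 1], [2, 3]]), np.ones((2, 2)))
        assert vals["SmallAreaHighGrayLevelEmphasis"] == pytest.approx((0.25 + 4 + 9) / 3)

    def test_glszm_constant_single_zone(self):
        vals = glszm_features(np.full((3, 4), 3, dtype=int), np.ones((3, 4)))
        assert vals["LargeAreaHighGrayLevelEmphasis"] == pytest.approx(9 * 144)

    def test_ngtdm_uniform_contrast_zero(self):
        vals = ngtdm_features(np.full((5, 5), 2, dtype=int), np.ones((5, 5)))
        assert vals["Contrast"] == 0.0
        assert vals["Busyness"] == 0.0

    def test_ngtdm_center_bump_example(self):
        img = np.ones((3, 3), dtype=int)
        img[1, 1] = 2
        vals = ngtdm_features(img, np.ones((3, 3)))
        assert vals["Contrast"] == pytest.approx(376 / 10935, rel=1e-9)


class TestTextureOracles:
    """Every family equals its independent brute-force oracle to 1e-9."""

    def test_glcm_matches_pair_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(8):
            levels, mask = random_level_image(rng, (6, 6))
            for d in DIRS_2D:
                mine = glcm_features(levels, mask, directions=[d])
                ref = oracle_glcm(levels, mask, d)
                for key in mine:
                    assert mine[key] == pytest.approx(ref[key], abs=1e-9)

    def test_glrlm_matches_run_scanner(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            levels, mask = random_level_image(rng, (5, 5))
            for d in DIRS_2D:
                mine = glrlm_features(levels, mask, directions=[d])
                ref = oracle_glrlm(levels, mask, d)
                for key in mine:
                    assert mine[key] == pytest.approx(ref[key], abs=1e-9)

    def test_glrlm_matches_run_scanner_3d(self):
        rng = np.random.default_rng(12)
        for _ in range(4):
            levels, mask = random_level_image(rng, (4, 4, 3))
            for d in DIRS_3D:
                mine = glrlm_features(levels, mask, directions=[d])
                ref = oracle_glrlm(levels, mask, d)
                for key in mine:
                    assert mine[key] == pytest.approx(ref[key], abs=1e-9)

    def test_glszm_matches_flood_fill(self):
        rng = np.random.default_rng(13)
        for shape, conn3d in (((4, 4, 2), True), ((6, 6), False)):
            for _ in range(6):
                levels, mask = random_level_image(rng, shape)
                mine = glszm_features(levels, mask)
                ref = oracle_glszm(levels, mask, connectivity_3d=conn3d)
                for key in mine:
                    assert mine[key] == pytest.approx(ref[key], abs=1e-9)

    def test_ngtdm_matches_neighborhood_sums(self):
        rng = np.random.default_rng(14)
        for shape, use3d in (((4, 4), False), ((4, 4, 3), True)):
            for _ in range(6):
                levels, mask = random_level_image(rng, shape)
                mine = ngtdm_features(levels, mask)
                ref = oracle_ngtdm(levels, mask, use_3d=use3d)
                for key in mine:
                    assert mine[key] == pytest.approx(ref[key], abs=1e-9)


class TestDiscretize:
    def test_fixed_bin_count_range(self):
        rng = np.random.default_rng(3)
        img = rng.random((8, 8)) * 100
        levels, ng = discretize(img, np.ones((8, 8)), DiscretizationSettings("fixed-bin-count", 8))
        assert ng == 8
        assert levels.min() >= 1 and levels.max() == 8

    def test_fixed_bin_width_anchoring(self):
        img = np.array([[0.0, 24.9, 25.0, 51.0]])
        levels, _ = discretize(
            img, np.ones((1, 4)), DiscretizationSettings("fixed-bin-width", 25.0)
        )
        assert levels.tolist() == [[1, 1, 2, 3]]


class TestExtractAll:
    def test_single_statistic_constant_roi(self, small_cohort):
        case = small_cohort.cases[0]
        cfg = FeatureConfig(
            filters=("original",),
            firstorder_stats=("Mean",),
            glcm=(), glrlm=(), glszm=(), ngtdm=(),
        )
        vol = case.volume
        const = vol.data.copy()
        const[case.mask.data.astype(bool)] = 7.0
        vol2 = type(vol)(data=const, spacing_mm=vol.spacing_mm)
        fv = extract_all(vol2, case.mask.data, cfg)
        assert fv == {"original_firstorder_Mean": 7.0}

    def test_feature_count_bookkeeping(self, small_cohort):
        case = small_cohort.cases[0]
        cfg = FeatureConfig()
        fv = extract_all(case.volume, case.truth_labels == 1, cfg)
        assert len(fv) == cfg.n_features()
        assert all(np.isfinite(v) for v in fv.values())

    def test_named_model_feature_finite_positive_on_phantom(self, small_cohort):
        case = small_cohort.cases[1]
        fv = extract_all(case.volume, case.truth_labels == 1)
        val = fv["wavelet-HLH_glrlm_LongRunEmphasis"]
        assert np.isfinite(val) and val > 0

    def test_empty_mask_warns_and_returns_empty(self, small_cohort):
        case = small_cohort.cases[0]
        with pytest.warns(UserWarning, match="empty"):
            fv = extract_all(case.volume, np.zeros(case.mask.shape, bool))
        assert fv == {}
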