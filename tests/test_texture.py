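import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from histotex.image import GrayImage
from histotex.texture import (
    COM_FEATURES,
    GRM_FEATURES,
    RLM_FEATURES,
    TextureConfig,
    TextureFeatureExtractor,
    com_features,
    compute_com,
    compute_grm,
    compute_rlm,
    extract_features,
    feature_names,
    grm_features,
    rlm_features,
)
from oracles import (
    com_counts_brute,
    com_features_brute,
    grm_features_brute,
    grm_magnitudes_brute,
    rlm_counts_brute,
    rlm_features_brute,
)

small_images = arrays(np.int64, (16, 16), elements=st.integers(0, 7))


def gray8(px):
    return GrayImage(np.asarray(px), levels=16)


class TestCooccurrence:
    def test_two_by_two_hand_example(self):
        img = GrayImage(np.array([[0, 1], [0, 1]]), levels=16)
        M = compute_com(img, (0, 1))
        assert M.counts[0, 1] == 2 and M.counts[1, 0] == 2
        assert M.counts.sum() == 4

    def test_constant_image_single_diagonal_entry(self):
        M = compute_com(gray8(np.full((8, 8), 5)), (1, 0))
        nz = np.argwhere(M.counts)
        assert nz.tolist() == [[5, 5]]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(px=small_images, dy=st.integers(-3, 3), dx=st.integers(-3, 3))
    def test_counts_match_bruteforce_and_are_symmetric(self, px, dy, dx):
        if dy == 0 and dx == 0:
            return
        M = compute_com(gray8(px), (dy, dx))
        np.testing.assert_array_equal(M.counts, com_counts_brute(px, dy, dx, 16))
        np.testing.assert_array_equal(M.counts, M.counts.T)

    def test_invalid_offsets_rejected(self, random_gray8):
        with pytest.raises(ValueError):
            compute_com(random_gray8, (0, 0))
        with pytest.raises(ValueError):
            compute_com(random_gray8, (0, 99))

    def test_matches_skimage_graycomatrix(self, random_gray8):
        """Independent library cross-check of the matrix construction."""
        skimage_feature = pytest.importorskip("skimage.feature")
        for d, angle, offset in [(1, 0.0, (0, 1)), (2, np.pi / 2, (-2, 0))]:
            ref = skimage_feature.graycomatrix(
                random_gray8.pixels.astype(np.uint8),
                distances=[d],
                angles=[angle],
                levels=16,
                symmetric=True,
            )[:, :, 0, 0]
            M = compute_com(random_gray8, offset)
            np.testing.assert_array_equal(M.counts, ref)


class TestComFeatures:
    def test_constant_image_closed_forms(self):
        f = com_features(compute_com(gray8(np.full((16, 16), 3)), (0, 1)))
        assert f["asm"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["correlation"] == 0.0  # zero-variance marginal convention

    def test_checkerboard_contrast_is_range_squared(self, checkerboard16):
        f = com_features(compute_com(checkerboard16, (0, 1)))
        assert f["contrast"] == pytest.approx(15**2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(px=small_images)
    def test_all_features_match_bruteforce(self, px):
        M = compute_com(gray8(px), (0, 1))
        got = com_features(M)
        want = com_features_brute(np.asarray(M.counts))
        for name in COM_FEATURES:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(px=small_images, dy=st.integers(-2, 2), dx=st.integers(1, 3))
    def test_feature_ranges(self, px, dy, dx):
        f = com_features(compute_com(gray8(px), (dy, dx)))
        assert 0 < f["asm"] <= 1
        assert 0 <= f["entropy"] <= 2 * np.log2(16)
        assert f["contrast"] >= 0
        assert -1 <= f["correlation"] <= 1
        assert 0 < f["idm"] <= 1


class TestRunLength:
    def test_hand_example_row(self):
        img = GrayImage(np.array([[1, 1, 2, 2, 2, 3]]), levels=16)
        R = compute_rlm(img, 0)
        assert R.counts[1, 2] == 1 and R.counts[2, 3] == 1 and R.counts[3, 1] == 1
        assert R.n_runs == 3

    def test_constant_image_one_run_per_row(self):
        R = compute_rlm(gray8(np.full((8, 8), 2)), 0)
        assert R.counts[2, 8] == 8
        assert rlm_features(R)["long_run_emphasis"] == pytest.approx(64)

    def test_all_length_one_runs_give_sre_one(self, checkerboard16):
        f = rlm_features(compute_rlm(checkerboard16, 0))
        assert f["short_run_emphasis"] == pytest.approx(1.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(px=small_images, direction=st.sampled_from([0, 45, 90, 135]))
    def test_counts_match_bruteforce_and_conserve_pixels(self, px, direction):
        R = compute_rlm(gray8(px), direction)
        np.testing.assert_array_equal(R.counts, rlm_counts_brute(px, direction, 16))
        r = np.arange(R.counts.shape[1])
        assert (R.counts * r).sum() == px.size

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(px=small_images, direction=st.sampled_from([0, 45, 90, 135]))
    def test_features_match_bruteforce(self, px, direction):
        R = compute_rlm(gray8(px), direction)
        got = rlm_features(R)
        want = rlm_features_brute(np.asarray(R.counts), px.size)
        for name in RLM_FEATURES:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name
        assert 0 < got["run_percentage"] <= 1


class TestGradient:
    def test_constant_image_all_zero(self):
        G = compute_grm(gray8(np.full((8, 8), 4)))
        assert G.magnitudes.max() == 0
        f = grm_features(G)
        assert f["mean"] == 0 and f["nonzero_pct"] == 0

    def test_horizontal_ramp_magnitude_two_everywhere(self):
        ramp = np.tile(np.arange(16), (16, 1))
        G = compute_grm(GrayImage(ramp, levels=16))
        np.testing.assert_allclose(G.magnitudes, 2.0)
        f = grm_features(G)
        assert f["variance"] == pytest.approx(0.0)
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0  # convention

    def test_transpose_symmetry(self, random_gray8):
        G = compute_grm(random_gray8)
        Gt = compute_grm(GrayImage(random_gray8.pixels.T, levels=16))
        np.testing.assert_allclose(Gt.magnitudes, G.magnitudes.T)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            compute_grm(GrayImage(np.zeros((2, 5), dtype=int), levels=16))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(px=small_images)
    def test_matches_bruteforce(self, px):
        G = compute_grm(gray8(px))
        np.testing.assert_allclose(G.magnitudes, grm_magnitudes_brute(px), atol=1e-12)
        got = grm_features(G)
        want = grm_features_brute(G.magnitudes)
        for name in GRM_FEATURES:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name


class TestExtractFeatures:
    def test_default_config_yields_65_named_features(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(32, 32)), levels=256)
        table = extract_features([img])
        assert table.shape == (1, 2 + 65)
        assert list(table.columns[:2]) == ["sample_id", "group"]
        assert table.columns.is_unique
        assert np.isfinite(table.iloc[0, 2:].astype(float)).all()

    def test_identical_images_give_identical_rows(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(32, 32)), levels=256)
        table = extract_features([img, img])
        assert table.iloc[0, 2:].equals(table.iloc[1, 2:])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            extract_features([])

    def test_shift_invariance_through_minmax_normalization(self, rng):
        px = rng.integers(10, 200, size=(32, 32))
        a = extract_features([GrayImage(px, levels=256)])
        b = extract_features([GrayImage(px + 40, levels=256)])
        np.testing.assert_allclose(
            a.iloc[0, 2:].astype(float), b.iloc[0, 2:].astype(float), rtol=1e-12
        )

    def test_transformer_matches_function_route(self, rng):
        px = rng.integers(0, 256, size=(32, 32))
        est = TextureFeatureExtractor().fit([px.astype(np.uint8)])
        out = est.transform([px.astype(np.uint8)])
        direct = extract_features([GrayImage(px, levels=256)]).drop(
            columns=["sample_id", "group"]
        )
        assert list(est.get_feature_names_out()) == feature_names(TextureConfig())
        np.testing.assert_allclose(out.to_numpy(), direct.to_numpy())
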