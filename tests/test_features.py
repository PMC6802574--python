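"""Pooling, fusion and normalization operators against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import taxofeat as tf
from taxofeat.backbone import BackboneSpec, FeatureMatrix
from taxofeat.errors import ConfigError, GeometryError, UsageError


def brute_force_pool(fm: np.ndarray, n: int, mode: str) -> np.ndarray:
    """Independent window-loop oracle for non-overlapping spatial pooling."""
    side, _, depth = fm.shape
    win = side // n
    out = np.empty((n, n, depth))
    for i in range(n):
        for j in range(n):
            window = fm[i * win : (i + 1) * win, j * win : (j + 1) * win]
            for f in range(depth):
                vals = window[:, :, f].ravel()
                out[i, j, f] = vals.mean() if mode == "average" else vals.max()
    return out


def _fm(arr, block="c4", tap="post_pool"):
    return FeatureMatrix(block, tap, np.asarray(arr, dtype=float))


class TestGlobalPool:
    def test_constant_matrix(self):
        fm = np.full((5, 5, 3), 2.5)
        for mode in ("average", "max"):
            assert np.allclose(tf.global_pool(fm, mode), 2.5)

    def test_hand_arithmetic(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
        assert tf.global_pool(fm, "average")[0] == 2.5
        assert tf.global_pool(fm, "max")[0] == 4.0

    def test_vector_length_equals_depth(self):
        fm = np.zeros((52, 52, 256))
        assert tf.global_pool(fm).shape == (256,)


class TestAlignToCommonGrid:
    def test_checkerboard_halves_to_half(self):
        board = np.indices((52, 52)).sum(axis=0) % 2
        out = tf.align_to_common_grid(_fm(board[..., None], "c3"), 26)
        assert np.allclose(out, 0.5)  # each 2x2 window holds two 1s and two 0s

    def test_reference_side_is_identity(self):
        fm = np.random.default_rng(0).random((26, 26, 4))
        assert np.array_equal(tf.align_to_common_grid(_fm(fm, "c4"), 26), fm)

    def test_matches_brute_force_on_toy(self):
        fm = np.random.default_rng(1).random((4, 4, 2))
        out = tf.align_to_common_grid(_fm(fm, "c3"), 2)
        assert np.allclose(out, brute_force_pool(fm, 2, "average"))

    def test_wrong_size_is_geometry_error(self):
        with pytest.raises(GeometryError):
            tf.align_to_common_grid(_fm(np.zeros((13, 13, 2)), "c5"), 26)


class TestZeroPad:
    def test_border_zero_interior_intact_sum_preserved(self):
        fm = np.random.default_rng(2).random((26, 26, 3)) + 1.0
        padded = tf.zero_pad_border(fm)
        assert padded.shape == (28, 28, 3)
        border = padded.sum() - padded[1:27, 1:27].sum()
        assert border == 0.0
        assert np.array_equal(padded[1:27, 1:27], fm)
        assert np.isclose(padded.sum(), fm.sum())


class TestSpatialPool:
    def test_constant_matrix(self):
        fm = np.full((28, 28, 2), 3.0)
        for n in (2, 4, 7, 14):
            for mode in ("average", "max"):
                assert np.allclose(tf.spatial_pool(fm, n, mode), 3.0)

    @pytest.mark.parametrize("n", [2, 4, 7, 14])
    @pytest.mark.parametrize("mode", ["average", "max"])
    def test_matches_brute_force(self, n, mode):
        fm = np.random.default_rng(n).random((28, 28, 2))
        assert np.allclose(tf.spatial_pool(fm, n, mode), brute_force_pool(fm, n, mode))

    def test_flattened_length_at_n7(self):
        fm = np.zeros((28, 28, 512))
        assert tf.flatten_features(tf.spatial_pool(fm, 7)).shape == (7 * 7 * 512,)
        assert 7 * 7 * 512 == 25088

    def test_disallowed_level_is_config_error(self):
        with pytest.raises(ConfigError):
            tf.spatial_pool(np.zeros((28, 28, 1)), 5)


class TestFlatten:
    def test_full_c4_flatten_length(self):
        fm = np.zeros((26, 26, 512))
        assert tf.flatten_features(fm).shape == (346112,)

    def test_one_by_one_is_the_pooled_vector(self):
        v = np.arange(8.0).reshape(1, 1, 8)
        assert np.array_equal(tf.flatten_features(v), v.ravel())

    def test_roundtrip_reshape(self):
        fm = np.random.default_rng(3).random((4, 4, 5))
        assert np.array_equal(tf.flatten_features(fm).reshape(4, 4, 5), fm)


class TestFuse:
    def test_length_additivity_and_order(self):
        a = tf.FeatureVector(np.zeros(256), "img", ("c3",))
        b = tf.FeatureVector(np.ones(512), "img", ("c4",))
        fused = tf.fuse([a, b])
        assert len(fused) == 768
        assert fused.blocks == ("c3", "c4")
        assert np.array_equal(fused.values[256:], np.ones(512))

    def test_single_vector_unchanged(self):
        a = tf.FeatureVector(np.arange(5.0))
        assert np.array_equal(tf.fuse([a]).values, a.values)

    def test_all_blocks_global_length_matches_spec_depths(self):
        spec = BackboneSpec()
        vecs = [
            tf.FeatureVector(np.zeros(f), "img", (f"c{i + 1}",))
            for i, f in enumerate(spec.filters_per_block)
        ]
        assert len(tf.fuse(vecs)) == sum(spec.filters_per_block) == 1472

    def test_mixed_images_is_usage_error(self):
        a = tf.FeatureVector(np.zeros(3), "img1")
        b = tf.FeatureVector(np.zeros(3), "img2")
        with pytest.raises(UsageError):
            tf.fuse([a, b])


class TestNormalization:
    def test_signed_sqrt_examples(self):
        assert np.allclose(tf.signed_sqrt(np.array([4.0, -9.0, 0.0])), [2.0, -3.0, 0.0])
        assert np.array_equal(tf.signed_sqrt(np.zeros(5)), np.zeros(5))

    def test_l2_examples(self):
        assert np.allclose(tf.l2_normalize(np.array([3.0, 4.0])), [0.6, 0.8])
        assert np.array_equal(tf.l2_normalize(np.zeros(4)), np.zeros(4))

    @given(arrays(np.float64, st.integers(1, 30),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    @settings(deadline=None)
    def test_signed_sqrt_preserves_signs(self, v):
        assert np.array_equal(np.sign(tf.signed_sqrt(v)), np.sign(v))

    @given(arrays(np.float64, st.integers(1, 30),
                  elements=st.floats(-100, 100, allow_nan=False)))
    @settings(deadline=None)
    def test_l2_output_norm_is_one_for_nonzero(self, v):
        if np.linalg.norm(v) > 0:
            assert np.isclose(np.linalg.norm(tf.l2_normalize(v)), 1.0)


class TestPoolingProperties:
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=30)
    def test_average_pool_commutes_with_positive_scaling(self, seed, scale):
        fm = np.random.default_rng(seed).random((28, 28, 2))
        assert np.allclose(
            tf.spatial_pool(fm * scale, 7, "average"),
            tf.spatial_pool(fm, 7, "average") * scale,
        )

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_max_pool_commutes_with_monotone_transform(self, seed):
        fm = np.random.default_rng(seed).random((28, 28, 2))
        assert np.allclose(
            tf.spatial_pool(np.exp(fm), 4, "max"), np.exp(tf.spatial_pool(fm, 4, "max"))
        )

    def test_level_one_ignores_zero_padding(self):
        """N=1 equals global average of the unpadded matrix: the zero border
        never enters the average."""
        fm = np.random.default_rng(9).random((26, 26, 3)) + 1.0
        v = tf.intermediate_vector(_fm(fm, "c4"), 26, level=1)
        assert np.allclose(v, fm.mean(axis=(0, 1)))
        padded_mean = tf.zero_pad_border(fm).mean(axis=(0, 1))
        assert not np.allclose(v, padded_mean)

    def test_level_28_flattens_without_reduction(self):
        fm = np.random.default_rng(10).random((26, 26, 2))
        v = tf.intermediate_vector(_fm(fm, "c4"), 26, level=28)
        assert v.shape == (28 * 28 * 2,)
        assert np.allclose(v, tf.flatten_features(tf.zero_pad_border(fm)))
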