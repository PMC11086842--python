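"""Min-max normalization and one-hot interval binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from binsight import (BinarizedMatrix, ExpressionMatrix, OneHotBinarizer,
                      bin_interval, binarize, minmax_normalize)
from conftest import literal_binarilization


def _matrix(X, labels=None):
    n, p = X.shape
    return ExpressionMatrix(X, [f"S{i}" for i in range(n)],
                            [f"G{j}" for j in range(p)], labels)


class TestMinMaxNormalize:
    def test_linear_rescale_endpoints(self):
        m = _matrix(np.array([[0.0], [5.0], [10.0]]))
        assert minmax_normalize(m).values[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        m = _matrix(np.array([[2.0, 1.0], [2.0, 3.0], [2.0, 5.0]]))
        out = minmax_normalize(m)
        assert np.all(out.values[:, 0] == 0.0)
        assert out.values[:, 1].tolist() == [0.0, 0.5, 1.0]

    def test_matches_per_element_recomputation(self, rng):
        X = rng.uniform(-3, 40, size=(20, 5))
        out = minmax_normalize(_matrix(X)).values
        for j in range(5):
            lo, hi = X[:, j].min(), X[:, j].max()
            np.testing.assert_allclose(out[:, j], (X[:, j] - lo) / (hi - lo))
        assert np.allclose(out.min(axis=0), 0) and np.allclose(out.max(axis=0), 1)

    def test_idempotent_on_nonconstant_columns(self, rng):
        m = _matrix(rng.uniform(0, 9, size=(15, 4)))
        once = minmax_normalize(m)
        twice = minmax_normalize(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_ids_and_labels_carried_through(self, small_matrix):
        out = minmax_normalize(small_matrix)
        assert out.gene_ids == small_matrix.gene_ids
        assert out.sample_ids == small_matrix.sample_ids
        np.testing.assert_array_equal(out.labels, small_matrix.labels)


class TestBinarize:
    def test_default_bin_count_is_ten_per_gene(self, small_matrix):
        b = binarize(minmax_normalize(small_matrix))
        assert b.values.shape[1] == small_matrix.n_genes * 10
        assert b.bin_map.K == 10

    @pytest.mark.parametrize("value,expected_bin", [(0.0, 0), (1.0, 9),
                                                    (0.05, 0), (0.95, 9)])
    def test_boundary_values_k10(self, value, expected_bin):
        m = _matrix(np.array([[value], [0.3]]))
        row = binarize(m, K=10).values[0]
        assert row[expected_bin] == 1 and row.sum() == 1

    def test_matches_literal_loop_oracle(self, rng):
        V = rng.uniform(0, 1, size=(5, 3))
        V[V == 1.0] = 0.5
        b = binarize(_matrix(V), K=4)
        np.testing.assert_array_equal(b.values, literal_binarilization(V, 4))
        assert np.all(b.values.reshape(5, 3, 4).sum(axis=2) == 1)

    def test_interior_boundary_goes_to_upper_tile(self):
        # value exactly k/K belongs to bin k by the ">=" membership test
        m = _matrix(np.array([[0.2], [0.7]]))
        b = binarize(m, K=10)
        assert b.values[0, 2] == 1 and b.values[1, 7] == 1

    def test_one_hot_conservation(self, rng):
        V = rng.uniform(0, 1, size=(30, 6))
        for K in (2, 4, 10):
            b = binarize(_matrix(V), K=K)
            np.testing.assert_array_equal(
                b.values.reshape(30, 6, K).sum(axis=2), 1)

    def test_out_of_range_error_names_sample_and_gene(self):
        m = _matrix(np.array([[0.5, 0.2], [0.1, 1.3]]))
        with pytest.raises(ValueError, match=r"S1.*G1"):
            binarize(m, K=10)

    def test_k_below_two_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="K"):
            binarize(minmax_normalize(small_matrix), K=1)

    def test_column_order_gene_major_named(self, small_matrix):
        b = binarize(minmax_normalize(small_matrix), K=3)
        assert b.column_ids[:4] == ["G0|bin0", "G0|bin1", "G0|bin2", "G1|bin0"]

    @settings(max_examples=25, deadline=None)
    @given(arrays(float, (7, 2), elements=st.floats(0, 1)),
           st.sampled_from([2, 5, 10]))
    def test_one_hot_property(self, V, K):
        b = binarize(_matrix(V), K=K)
        assert np.all(b.values.reshape(7, 2, K).sum(axis=2) == 1)


class TestBinInterval:
    def test_tiles(self):
        m = _matrix(np.random.default_rng(0).uniform(0, 1, (3, 1)))
        bm = binarize(m, K=10).bin_map
        assert bin_interval(bm, 0) == ("G0", 0.0, 0.1, False)
        gene, lo, hi, closed = bin_interval(bm, 9)
        assert (gene, lo, hi, closed) == ("G0", 0.9, 1.0, True)

    def test_tiling_disjoint_and_covering(self):
        m = _matrix(np.array([[0.1, 0.2], [0.9, 0.3]]))
        bm = binarize(m, K=7).bin_map
        for g in range(2):
            ivals = [bin_interval(bm, g * 7 + k) for k in range(7)]
            assert ivals[0][1] == 0.0 and ivals[-1][2] == 1.0
            for a, b in zip(ivals[:-1], ivals[1:]):
                assert a[2] == b[1]  # contiguous, no overlap

    def test_assigned_column_contains_value_roundtrip(self, rng):
        V = rng.uniform(0, 1, size=(1000, 1))
        b = binarize(_matrix(np.vstack([V, [[0.0]], [[1.0]]])), K=10)
        cols = np.argmax(b.values, axis=1)
        for i, c in enumerate(cols):
            _, lo, hi, closed = bin_interval(b.bin_map, int(c))
            v = b.values  # noqa: F841 - keep matrix alive
            val = np.vstack([V, [[0.0]], [[1.0]]])[i, 0]
            assert lo <= val and (val < hi or (closed and val <= hi))

    def test_out_of_range_column(self, small_matrix):
        bm = binarize(minmax_normalize(small_matrix), K=4).bin_map
        with pytest.raises(IndexError):
            bin_interval(bm, len(bm))


class TestOneHotBinarizerEstimator:
    def test_sklearn_roundtrip_equals_function_path(self, small_matrix):
        est = OneHotBinarizer(n_bins=10)
        out = est.fit_transform(small_matrix.to_frame())
        ref = binarize(minmax_normalize(small_matrix), K=10)
        np.testing.assert_array_equal(out, ref.values)
        assert list(est.get_feature_names_out()) == ref.column_ids

    def test_clip_mode_handles_out_of_fit_range(self, small_matrix):
        est = OneHotBinarizer(n_bins=10, clip=True).fit(small_matrix.values)
        shifted = small_matrix.values * 1.5 - 2.0
        out = est.transform(shifted)
        assert np.all(out.reshape(20, 5, 10).sum(axis=2) == 1)

    def test_get_params_roundtrip(self):
        est = OneHotBinarizer(n_bins=4, clip=True)
        assert OneHotBinarizer(**est.get_params()).n_bins == 4

    def test_strict_mode_raises_outside_fit_range(self, small_matrix):
        est = OneHotBinarizer(n_bins=10).fit(small_matrix.values)
        with pytest.raises(ValueError, match="outside"):
            est.transform(small_matrix.values + 100.0)


class TestBinarizedMatrixInvariants:
    def test_column_count_must_match_map(self, small_matrix):
        ref = binarize(minmax_normalize(small_matrix), K=4)
        with pytest.raises(ValueError):
            BinarizedMatrix(ref.values[:, :-1], ref.bin_map,
                            list(small_matrix.sample_ids))
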