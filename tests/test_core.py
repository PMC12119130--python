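"""Core types and operators: clipping, sampling, normalization, ion images."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from msicomplete import (
    LowRankFactors,
    ObservationMask,
    SolverConfig,
    SpectraMatrix,
    apply_mask,
    clip,
    ion_image,
    reconstruct,
    tic_normalize,
)

nonneg_matrices = arrays(
    np.float64,
    st.tuples(st.integers(1, 6), st.integers(1, 6)),
    elements=st.floats(0.0, 100.0, allow_nan=False),
)


class TestSpectraMatrix:
    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError, match="non-negative"):
            SpectraMatrix.from_dense(np.array([[1.0, -2.0]]))

    def test_rejects_duplicate_pixel_coords(self):
        with pytest.raises(ValueError, match="unique"):
            SpectraMatrix(
                sp.csr_matrix(np.ones((2, 2))),
                np.array([[0, 0], [0, 0]]),
                np.array([1.0, 2.0]),
            )

    def test_rejects_decreasing_mz_axis(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            SpectraMatrix.from_dense(np.ones((1, 2)), mz_axis=np.array([2.0, 1.0]))


class TestClip:
    def test_thresholds_entries_below_k(self, small_matrix):
        out = clip(small_matrix, 1.0)
        np.testing.assert_array_equal(out.toarray(), [[1.0, 0.0], [2.0, 3.0]])
        assert out.values.nnz == 3  # the clipped entry leaves sparse storage

    def test_zero_threshold_is_identity(self, small_matrix):
        np.testing.assert_array_equal(
            clip(small_matrix, 0.0).toarray(), small_matrix.toarray()
        )

    def test_threshold_above_max_empties_matrix(self, small_matrix):
        out = clip(small_matrix, 100.0)
        assert out.values.nnz == 0

    def test_negative_threshold_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            clip(small_matrix, -1.0)

    @settings(max_examples=50, derandomize=True)
    @given(dense=nonneg_matrices, k1=st.floats(0, 50), k2=st.floats(0, 50))
    def test_stored_entries_monotone_in_threshold(self, dense, k1, k2):
        M = SpectraMatrix.from_dense(dense)
        lo, hi = sorted([k1, k2])
        assert clip(M, hi).values.nnz <= clip(M, lo).values.nnz


class TestApplyMask:
    def test_full_mask_is_identity(self, small_matrix):
        mask = ObservationMask.full(small_matrix.shape)
        np.testing.assert_array_equal(
            apply_mask(small_matrix, mask).toarray(), small_matrix.toarray()
        )

    def test_empty_mask_zeroes_everything(self, small_matrix):
        mask = ObservationMask.empty(small_matrix.shape)
        assert apply_mask(small_matrix, mask).values.nnz == 0

    def test_keeps_only_selected_entries(self):
        M = SpectraMatrix.from_dense(np.array([[3.0, 4.0], [5.0, 6.0]]))
        mask = ObservationMask(np.array([0, 1]), np.array([0, 1]), (2, 2))
        np.testing.assert_array_equal(
            apply_mask(M, mask).toarray(), [[3.0, 0.0], [0.0, 6.0]]
        )

    def test_shape_mismatch_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="shape"):
            apply_mask(small_matrix, ObservationMask.full((3, 3)))

    @settings(max_examples=50, derandomize=True)
    @given(dense=nonneg_matrices, seed=st.integers(0, 100))
    def test_idempotent_and_complement_partitions(self, dense, seed):
        M = SpectraMatrix.from_dense(dense)
        m, n = M.shape
        rng = np.random.default_rng(seed)
        lin = rng.choice(m * n, size=rng.integers(0, m * n + 1), replace=False)
        mask = ObservationMask.from_linear(lin, (m, n))
        once = apply_mask(M, mask)
        twice = apply_mask(once, mask)
        assert (once.values != twice.values).nnz == 0
        total = (
            apply_mask(M, mask).toarray() + apply_mask(M, mask.complement()).toarray()
        )
        np.testing.assert_array_equal(total, dense)


class TestObservationMask:
    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ObservationMask(np.array([0, 0]), np.array([1, 1]), (2, 2))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            ObservationMask(np.array([5]), np.array([0]), (2, 2))

    def test_extract_factors_matches_dense_product(self):
        rng = np.random.default_rng(0)
        U, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        V, _ = np.linalg.qr(rng.standard_normal((6, 3)))
        F = LowRankFactors(U, np.array([3.0, 2.0, 1.0]), V)
        mask = ObservationMask.from_linear(np.arange(0, 48, 5), (8, 6))
        np.testing.assert_allclose(
            mask.extract_factors(F), F.dense()[mask.rows, mask.cols], atol=1e-12
        )


class TestTicNormalize:
    def test_constant_row_scaled_by_trimmed_sum(self):
        M = SpectraMatrix.from_dense(np.full((1, 8), 2.0))
        out = tic_normalize(M)
        # all values equal -> trimmed set is the whole row of 8 entries
        np.testing.assert_allclose(out.toarray(), np.full((1, 8), 1.0 / 8.0))

    def test_all_zero_row_unchanged_with_warning(self):
        M = SpectraMatrix.from_dense(np.array([[0.0, 0.0], [1.0, 3.0]]))
        with pytest.warns(RuntimeWarning, match="zero trimmed TIC"):
            out = tic_normalize(M)
        np.testing.assert_array_equal(out.toarray()[0], [0.0, 0.0])

    def test_trimmed_sum_is_one_after_normalization(self):
        rng = np.random.default_rng(1)
        M = SpectraMatrix.from_dense(rng.uniform(0.1, 10.0, (5, 40)))
        out = tic_normalize(M)
        for i in range(5):
            row = out.values[i].toarray().ravel()
            nz = row[row > 0]
            lo, hi = np.percentile(nz, [5, 95])
            assert abs(nz[(nz >= lo) & (nz <= hi)].sum() - 1.0) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        M = SpectraMatrix.from_dense(rng.uniform(0.0, 5.0, (4, 30)))
        once = tic_normalize(M)
        twice = tic_normalize(once)
        np.testing.assert_allclose(twice.toarray(), once.toarray(), atol=1e-9)


class TestIonImage:
    def test_row_major_grid_round_trip(self):
        M = SpectraMatrix(
            sp.csr_matrix(np.array([[1.0], [2.0], [3.0], [4.0]])),
            np.array([[0, 0], [1, 0], [0, 1], [1, 1]]),  # (x, y)
            np.array([500.0]),
        )
        np.testing.assert_array_equal(ion_image(M, 0), [[1.0, 2.0], [3.0, 4.0]])

    def test_single_pixel(self):
        M = SpectraMatrix(
            sp.csr_matrix(np.array([[7.0]])), np.array([[3, 5]]), np.array([1.0])
        )
        np.testing.assert_array_equal(ion_image(M, 0), [[7.0]])

    def test_missing_grid_positions_are_nan(self):
        M = SpectraMatrix(
            sp.csr_matrix(np.array([[1.0], [2.0], [3.0]])),
            np.array([[0, 0], [1, 0], [0, 1]]),
            np.array([1.0]),
        )
        img = ion_image(M, 0)
        assert np.isnan(img[1, 1])
        assert img[0, 0] == 1.0 and img[0, 1] == 2.0 and img[1, 0] == 3.0

    def test_out_of_range_bin_rejected(self, small_matrix):
        with pytest.raises(IndexError):
            ion_image(small_matrix, 2)


class TestReconstruct:
    def test_rank_one_outer_product(self):
        u = np.array([[1.0], [2.0]]) / np.sqrt(5)
        v = np.array([[3.0], [4.0]]) / 5.0
        F = LowRankFactors(u, np.array([2 * np.sqrt(5) * 5.0]), v)
        np.testing.assert_allclose(reconstruct(F), [[6.0, 8.0], [12.0, 16.0]])

    def test_empty_row_subset(self):
        F = LowRankFactors.zero((3, 4))
        assert reconstruct(F, rows=[]).shape == (0, 4)

    def test_exact_rank_r_round_trip(self):
        rng = np.random.default_rng(5)
        T = rng.uniform(0, 1, (12, 4)) @ rng.uniform(0, 1, (9, 4)).T
        U, s, Vt = np.linalg.svd(T, full_matrices=False)
        F = LowRankFactors(U[:, :4], s[:4], Vt[:4].T)
        assert np.linalg.norm(reconstruct(F) - T) / np.linalg.norm(T) < 1e-10

    def test_out_of_range_subset_rejected(self):
        F = LowRankFactors.zero((3, 4))
        with pytest.raises(IndexError):
            reconstruct(F, rows=[5])


class TestSolverConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"delta": -1.0},
            {"tau": 0.0},
            {"sigma": -0.5},
            {"tol": 1.5},
            {"max_iter": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)
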