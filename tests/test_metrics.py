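"""Error metrics, spectral error scores, and storage accounting."""

import numpy as np
import pytest

from msicomplete import (
    DegenerateSubsetError,
    LowRankFactors,
    ObservationMask,
    SpectraMatrix,
    error_report,
    mask_uniform,
    model_error,
    spectral_error_scores,
    storage_accounting,
    truncated_svd,
)


def factors_of(dense: np.ndarray) -> LowRankFactors:
    U, s, Vt = np.linalg.svd(dense, full_matrices=False)
    keep = s > 1e-12
    return LowRankFactors(U[:, keep], s[keep], Vt[keep].T)


class TestModelError:
    def test_exact_model_scores_zero_on_every_subset(self):
        dense = np.array([[1.0, 2.0], [3.0, 4.0]])
        M = SpectraMatrix.from_dense(dense)
        F = factors_of(dense)
        mask = ObservationMask(np.array([0]), np.array([1]), (2, 2))
        for subset in ("observed", "missing", "all"):
            assert model_error(M, F, mask, subset) < 1e-10

    def test_zero_model_scores_hundred_percent(self):
        M = SpectraMatrix.from_dense(np.array([[1.0, 2.0], [3.0, 4.0]]))
        F = LowRankFactors.zero((2, 2))
        mask = ObservationMask(np.array([0]), np.array([1]), (2, 2))
        for subset in ("observed", "missing", "all"):
            assert model_error(M, F, mask, subset) == pytest.approx(100.0)

    def test_hand_computed_partial_model(self):
        # reference (3, 4), model (3, 0): error = 4/5 = 80%
        M = SpectraMatrix.from_dense(np.array([[3.0, 4.0]]))
        F = factors_of(np.array([[3.0, 0.0]]))
        mask = ObservationMask.full((1, 2))
        assert model_error(M, F, mask, "observed") == pytest.approx(80.0)

    def test_zero_denominator_raises_degenerate_signal(self):
        M = SpectraMatrix.from_dense(np.array([[0.0, 1.0]]))
        F = LowRankFactors.zero((1, 2))
        mask = ObservationMask(np.array([0]), np.array([0]), (1, 2))  # only the 0
        with pytest.raises(DegenerateSubsetError):
            model_error(M, F, mask, "observed")

    def test_pythagorean_decomposition_over_disjoint_supports(self):
        rng = np.random.default_rng(0)
        dense = rng.uniform(0.1, 2.0, (12, 9))
        M = SpectraMatrix.from_dense(dense)
        F = truncated_svd(M, 3)
        mask = mask_uniform(M, 0.4, seed=0)
        e_all = model_error(M, F, mask, "all")
        e_obs = model_error(M, F, mask, "observed")
        e_mis = model_error(M, F, mask, "missing")
        n_all = np.linalg.norm(dense) ** 2
        n_obs = np.linalg.norm(dense[mask.rows, mask.cols]) ** 2
        comp = mask.complement()
        n_mis = np.linalg.norm(dense[comp.rows, comp.cols]) ** 2
        lhs = e_all**2 * n_all
        rhs = e_obs**2 * n_obs + e_mis**2 * n_mis
        assert abs(lhs - rhs) <= 1e-9 * lhs
        assert min(e_obs, e_mis) <= e_all <= max(e_obs, e_mis)


class TestSpectralErrorScores:
    def test_exact_model_scores_all_zero(self):
        rng = np.random.default_rng(1)
        dense = rng.uniform(0, 1, (5, 30))
        M = SpectraMatrix.from_dense(dense)
        scores, degenerate = spectral_error_scores(M, factors_of(dense), k=10)
        assert not degenerate.any()
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_hand_computed_dataset_top_k(self):
        # column sums (3, 4, 5): top-2 bins are {1, 2}
        ref = np.array([[3.0, 4.0, 0.0], [0.0, 0.0, 5.0]])
        X = factors_of(np.array([[3.0, 0.0, 0.0], [0.0, 0.0, 5.0]]))
        M = SpectraMatrix.from_dense(ref)
        scores, degenerate = spectral_error_scores(M, X, "dataset_top_k", k=2)
        np.testing.assert_allclose(scores, [100.0, 0.0])
        assert not degenerate.any()

    def test_per_spectrum_selector_saturates_to_full_row_error(self):
        rng = np.random.default_rng(2)
        ref = np.zeros((3, 20))
        ref[:, :5] = rng.uniform(0.5, 1.0, (3, 5))  # support fits in k
        M = SpectraMatrix.from_dense(ref)
        X = factors_of(ref * 0.9)
        scores, _ = spectral_error_scores(M, X, "per_spectrum_top_k", k=8)
        full_row = [
            100 * np.linalg.norm(ref[i] - 0.9 * ref[i]) / np.linalg.norm(ref[i])
            for i in range(3)
        ]
        np.testing.assert_allclose(scores, full_row, rtol=1e-10)

    def test_zero_restricted_norm_rows_flagged(self):
        ref = np.array([[0.0, 0.0, 1.0], [1.0, 2.0, 3.0]])
        M = SpectraMatrix.from_dense(ref)
        X = factors_of(ref)
        # dataset top-2 bins are {1, 2}; row 0 has zero norm there? sums (1,2,4)
        scores, degenerate = spectral_error_scores(M, X, "dataset_top_k", k=1)
        # top-1 bin is 2 (sum 4); both rows have mass there -> no flags
        assert not degenerate.any()
        M2 = SpectraMatrix.from_dense(np.array([[0.0, 5.0], [0.0, 0.0]]))
        scores2, deg2 = spectral_error_scores(
            M2, LowRankFactors.zero((2, 2)), "dataset_top_k", k=1
        )
        assert deg2[1] and not deg2[0]
        assert np.isnan(scores2[1])


class TestStorageAccounting:
    """The printed footprints and compression factors of both published
    datasets follow from GB = 1e9 bytes and 4-byte values."""

    def test_ftircr_dense_footprint(self):
        rec = storage_accounting(3780, 1_372_421, "dense")
        assert round(rec.footprint_gb, 4) == 20.7510

    def test_ftircr_peak_picking_rows(self):
        rec100 = storage_accounting(3780, 1_372_421, "peak_columns", 100)
        assert round(rec100.footprint_gb, 4) == 0.0015
        assert rec100.compression_dense == 13_724
        rec123 = storage_accounting(3780, 1_372_421, "peak_columns", 123)
        assert round(rec123.footprint_gb, 4) == 0.0019
        assert rec123.compression_dense == 11_158

    def test_tof_dense_footprint(self):
        rec = storage_accounting(1_320_876, 312_249, "dense")
        assert round(rec.footprint_gb, 3) == 1649.769

    def test_tof_two_factor_rows(self):
        svt = storage_accounting(1_320_876, 312_249, "two_factor", 100)
        assert round(svt.footprint_gb, 3) == 0.653
        assert svt.compression_dense == 2525
        fpc = storage_accounting(1_320_876, 312_249, "two_factor", 105)
        assert round(fpc.footprint_gb, 3) == 0.686
        assert fpc.compression_dense == 2405

    def test_compression_rounds_half_away_from_zero(self):
        # 1 372 421 / 123 = 11 157.9... -> 11 158
        rec = storage_accounting(3780, 1_372_421, "peak_columns", 123)
        assert rec.compression_dense == 11_158

    def test_missing_k_rejected(self):
        with pytest.raises(ValueError):
            storage_accounting(10, 10, "two_factor")


class TestErrorReport:
    def test_report_assembles_consistent_fields(self):
        rng = np.random.default_rng(3)
        dense = rng.uniform(0.1, 1.0, (15, 12))
        M = SpectraMatrix.from_dense(dense)
        F = truncated_svd(M, 4)
        mask = mask_uniform(M, 0.5, seed=3)
        rep = error_report(M, F, mask, nnz_sparse=M.values.nnz)
        assert rep.rank == 4
        assert rep.reconstruction_pct >= 0 and rep.imputation_pct >= 0
        assert (
            min(rep.reconstruction_pct, rep.imputation_pct)
            <= rep.global_pct
            <= max(rep.reconstruction_pct, rep.imputation_pct)
        )
        assert rep.compression_dense is not None
        assert rep.compression_sparse is not None
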