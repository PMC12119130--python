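"""Evaluation arithmetic: relative errors, spectral error scores, storage.

Three relative Frobenius errors (in percent) summarise how well a low-rank
model ``X`` matches a reference matrix:

* reconstruction error — on the observed entries (Omega),
* imputation error — on the missing entries (Omega^c),
* global error — on all entries.

Because Omega and Omega^c are disjoint, the squared global error decomposes
exactly (Pythagoras) into the observed and missing contributions.

Storage accounting follows the conventions that reproduce the published
footprints: GB means 1e9 bytes, values are 4-byte floats, a two-factor model
costs ``(m + n) * k`` values, a ``k``-column peak-picking representation
costs ``m * k``, and compression factors are rounded half away from zero to
integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np

from .core import LowRankFactors, ObservationMask, SpectraMatrix, reconstruct

__all__ = [
    "ErrorReport",
    "DegenerateSubsetError",
    "model_error",
    "spectral_error_scores",
    "storage_accounting",
    "StorageRecord",
    "sparse_csc_footprint_gb",
    "error_report",
]

_ROW_CHUNK = 256


class DegenerateSubsetError(ValueError):
    """The reference has zero norm on the requested index subset."""


@dataclass
class ErrorReport:
    """Error and storage summary for one model of one dataset."""

    reconstruction_pct: float
    imputation_pct: Optional[float]
    global_pct: float
    rank: int
    footprint_gb: float
    compression_dense: Optional[int]
    compression_sparse: Optional[int] = None


@dataclass
class StorageRecord:
    representation: str
    bytes: int
    footprint_gb: float
    compression_dense: Optional[int]


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def _chunk_norms(
    reference: SpectraMatrix,
    X: LowRankFactors,
    mask: Optional[ObservationMask],
    subset: str,
) -> Tuple[float, float]:
    """Accumulate ||P_subset(ref - X)||^2 and ||P_subset(ref)||^2 blockwise."""
    m, n = reference.shape
    mask_csr = mask.to_bool_csr() if mask is not None else None
    num2 = den2 = 0.0
    for start in range(0, m, _ROW_CHUNK):
        stop = min(start + _ROW_CHUNK, m)
        rows = np.arange(start, stop)
        ref_block = reference.values[start:stop].toarray()
        x_block = reconstruct(X, rows=rows)
        diff = ref_block - x_block
        if subset != "all":
            sel = mask_csr[start:stop].toarray()
            if subset == "missing":
                sel = ~sel
            diff = np.where(sel, diff, 0.0)
            ref_block = np.where(sel, ref_block, 0.0)
        num2 += float(np.sum(diff * diff))
        den2 += float(np.sum(ref_block * ref_block))
    return num2, den2


def model_error(
    reference: SpectraMatrix,
    X: LowRankFactors,
    mask: Optional[ObservationMask] = None,
    subset: Literal["observed", "missing", "all"] = "all",
) -> float:
    """Relative Frobenius error of ``X`` against ``reference`` (percent).

    ``subset`` restricts the comparison to the observed entries (Omega), the
    missing entries (Omega^c) or all entries.  The model is evaluated
    blockwise so the full dense product is never materialized.
    """
    if subset not in ("observed", "missing", "all"):
        raise ValueError(f"unknown subset {subset!r}")
    if subset != "all" and mask is None:
        raise ValueError(f"subset={subset!r} requires an observation mask")
    if X.shape != reference.shape:
        raise ValueError("factor shape does not match reference")
    num2, den2 = _chunk_norms(reference, X, mask, subset)
    if den2 == 0.0:
        raise DegenerateSubsetError(
            f"reference norm is zero on subset {subset!r}; the relative error "
            "is undefined"
        )
    return 100.0 * math.sqrt(num2 / den2)


def spectral_error_scores(
    reference: SpectraMatrix,
    X: LowRankFactors,
    selector: Literal["dataset_top_k", "per_spectrum_top_k"] = "dataset_top_k",
    k: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-spectrum relative errors (percent) restricted to the top-``k`` bins.

    ``dataset_top_k`` scores every spectrum on the ``k`` m/z-bins with the
    largest total ion current across the dataset; ``per_spectrum_top_k``
    scores each spectrum on its own ``k`` most intense bins.  Returns
    ``(scores, degenerate)`` where ``degenerate`` flags rows whose restricted
    reference norm is zero (their score is NaN).
    """
    m, n = reference.shape
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= {n}, got {k}")
    if selector not in ("dataset_top_k", "per_spectrum_top_k"):
        raise ValueError(f"unknown selector {selector!r}")

    scores = np.full(m, np.nan)
    degenerate = np.zeros(m, dtype=bool)

    if selector == "dataset_top_k":
        colsums = np.asarray(reference.values.sum(axis=0)).ravel()
        top = np.lexsort((np.arange(n), -colsums))[:k]
        top = np.sort(top)

    ref_csr = reference.values.tocsr()
    for i in range(m):
        row = np.asarray(ref_csr[i].todense()).ravel()
        if selector == "per_spectrum_top_k":
            bins = np.lexsort((np.arange(n), -row))[:k]
        else:
            bins = top
        ref_sel = row[bins]
        x_sel = reconstruct(X, rows=[i], cols=bins).ravel()
        den = np.linalg.norm(ref_sel)
        if den == 0.0:
            degenerate[i] = True
            continue
        scores[i] = 100.0 * np.linalg.norm(ref_sel - x_sel) / den
    return scores, degenerate


def storage_accounting(
    m: int,
    n: int,
    representation: Literal["dense", "peak_columns", "two_factor"],
    k: Optional[int] = None,
    bytes_per_value: int = 4,
) -> StorageRecord:
    """Storage footprint and dense-format compression factor.

    ``dense`` stores all ``m*n`` values; ``peak_columns`` the ``m x k``
    reduced matrix of a ``k``-peak picking; ``two_factor`` the ``m x k`` and
    ``n x k`` factor matrices of a rank-``k`` model (singular values are
    negligible and not counted).  Footprints are in GB = 1e9 bytes;
    compression factors are dense bytes over representation bytes, rounded
    half away from zero.
    """
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    dense_bytes = m * n * bytes_per_value
    if representation == "dense":
        rep_bytes = dense_bytes
        compression = None
    elif representation == "peak_columns":
        if k is None or k <= 0:
            raise ValueError("peak_columns requires a positive k")
        rep_bytes = m * k * bytes_per_value
        compression = _round_half_away(dense_bytes / rep_bytes)
    elif representation == "two_factor":
        if k is None or k <= 0:
            raise ValueError("two_factor requires a positive k")
        rep_bytes = (m + n) * k * bytes_per_value
        compression = _round_half_away(dense_bytes / rep_bytes)
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return StorageRecord(
        representation=representation,
        bytes=rep_bytes,
        footprint_gb=rep_bytes / 1e9,
        compression_dense=compression,
    )


def sparse_csc_footprint_gb(
    nnz: int, n_cols: int, bytes_per_value: int = 4, bytes_per_index: int = 4
) -> float:
    """Footprint of a compressed-sparse-column store (values + row indices +
    64-bit column pointers), in GB.  A bookkeeping convention of this package;
    vendor sparse formats differ."""
    return (nnz * (bytes_per_value + bytes_per_index) + (n_cols + 1) * 8) / 1e9


def error_report(
    reference: SpectraMatrix,
    X: LowRankFactors,
    mask: Optional[ObservationMask] = None,
    nnz_sparse: Optional[int] = None,
) -> ErrorReport:
    """Assemble the standard evaluation row for one model."""
    m, n = reference.shape
    global_pct = model_error(reference, X, mask, "all")
    if mask is not None and 0 < len(mask) < m * n:
        recon_pct = model_error(reference, X, mask, "observed")
        try:
            imput_pct = model_error(reference, X, mask, "missing")
        except DegenerateSubsetError:
            imput_pct = None
    else:
        recon_pct = global_pct
        imput_pct = None
    storage = storage_accounting(m, n, "two_factor", max(X.rank, 1))
    compression_sparse = None
    if nnz_sparse is not None:
        sparse_gb = sparse_csc_footprint_gb(nnz_sparse, n)
        compression_sparse = _round_half_away(sparse_gb / storage.footprint_gb)
    return ErrorReport(
        reconstruction_pct=recon_pct,
        imputation_pct=imput_pct,
        global_pct=global_pct,
        rank=X.rank,
        footprint_gb=storage.footprint_gb,
        compression_dense=storage.compression_dense,
        compression_sparse=compression_sparse,
    )
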