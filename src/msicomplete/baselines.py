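"""Peak picking and truncated SVD: the classical data-reduction baselines.

Peak picking reduces every spectrum to the same ``k`` m/z-bins, chosen from
the dataset-wide summed spectrum; it is a column-selection low-rank
approximation and therefore can never beat the truncated SVD, which is the
Frobenius-optimal rank-``k`` approximation (Eckart–Young).
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

import numpy as np
import scipy.linalg
import scipy.sparse.linalg as spla

from .core import LowRankFactors, SpectraMatrix

__all__ = ["pick_peaks", "truncated_svd", "truncate_rank"]

_DENSE_CUTOFF = 500


def pick_peaks(
    M: SpectraMatrix,
    k: int,
    mode: Literal["top_bins", "local_maxima"] = "top_bins",
    window_halfwidth: Optional[int] = None,
) -> Tuple[np.ndarray, SpectraMatrix]:
    """Select the ``k`` most intense m/z-bins of the dataset-wide summed spectrum.

    ``top_bins`` ranks every bin by its column sum; ``local_maxima`` first
    restricts candidates to bins whose summed intensity strictly exceeds both
    neighbours (a minimal peak criterion).  Ties are broken toward the lower
    bin index.  Returns the selected bin indices in ascending m/z order and
    the matrix restricted to those columns.

    ``window_halfwidth`` optionally integrates each picked bin over a
    ``+-halfwidth`` bin window (off by default; the plain baseline picks bare
    bins of the summed spectrum).
    """
    n = M.n_bins
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= {n}, got {k}")
    colsums = np.asarray(M.values.sum(axis=0)).ravel()

    if mode == "top_bins":
        candidates = np.arange(n)
    elif mode == "local_maxima":
        interior = np.arange(1, n - 1)
        is_max = (colsums[interior] > colsums[interior - 1]) & (
            colsums[interior] > colsums[interior + 1]
        )
        candidates = interior[is_max]
        if k > candidates.size:
            raise ValueError(
                f"requested {k} peaks but only {candidates.size} local maxima "
                "are available"
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # sort by (-sum, bin index): lower index wins ties
    order = np.lexsort((candidates, -colsums[candidates]))[:k]
    picked = np.sort(candidates[order])

    if window_halfwidth:
        cols = []
        for j in picked:
            lo, hi = max(0, j - window_halfwidth), min(n, j + window_halfwidth + 1)
            cols.append(np.asarray(M.values[:, lo:hi].sum(axis=1)).ravel())
        reduced_vals = np.column_stack(cols)
    else:
        reduced_vals = M.values[:, picked]
    reduced = SpectraMatrix(
        reduced_vals,
        M.pixel_coords,
        M.mz_axis[picked],
        {**M.metadata, "picked_bins": picked.tolist()},
    )
    return picked, reduced


def truncated_svd(M: SpectraMatrix, k: int) -> LowRankFactors:
    """Best rank-``k`` approximation of ``M`` in the Frobenius norm.

    Small matrices take the direct (GESDD) path; larger ones use a sparse
    iterative partial SVD.  Both paths agree to high relative accuracy.
    """
    m, n = M.shape
    if not (1 <= k <= min(m, n)):
        raise ValueError(f"need 1 <= k <= {min(m, n)}, got {k}")
    if min(m, n) <= _DENSE_CUTOFF or k >= min(m, n) - 1:
        U, s, Vt = scipy.linalg.svd(
            M.values.toarray(), full_matrices=False, lapack_driver="gesdd"
        )
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
    else:
        try:
            U, s, Vt = spla.svds(M.values.tocsc(), k=k)
        except spla.ArpackNoConvergence as exc:  # pragma: no cover
            raise RuntimeError(
                f"iterative partial SVD did not converge at k={k}"
            ) from exc
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    return LowRankFactors(U, s, Vt.T)


def truncate_rank(F: LowRankFactors, r: int) -> LowRankFactors:
    """Keep the ``r`` largest singular triplets of a factorization."""
    if r > F.rank:
        raise ValueError(f"requested rank {r} exceeds factor rank {F.rank}")
    if r < 0:
        raise ValueError("rank must be >= 0")
    return LowRankFactors(F.left[:, :r], F.singvals[:r], F.right[:, :r])
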