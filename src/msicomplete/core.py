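"""Core domain types and operators for sparse imaging-mass-spectrometry matrices.

An IMS dataset is modelled as a pixels-by-(m/z-bin) matrix ``M`` whose rows are
mass spectra and whose columns, rearranged onto the pixel grid, are ion images.
Acquisition-time intensity clipping zeroes every entry below a threshold,
which both sparsifies the data and — when treated honestly — turns the dataset
into a matrix with *missing* entries.  The two operators that formalise this
are :func:`clip` (the instrument-side thresholding) and :func:`apply_mask`
(the sampling operator ``P_Omega`` used by the completion solvers).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "SpectraMatrix",
    "ObservationMask",
    "LowRankFactors",
    "SolverConfig",
    "clip",
    "apply_mask",
    "tic_normalize",
    "ion_image",
    "reconstruct",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpectraMatrix:
    """Pixel-by-m/z-bin intensity matrix with spatial coordinates.

    Parameters
    ----------
    values
        ``m x n`` sparse matrix of non-negative ion intensities (CSR).
    pixel_coords
        ``(m, 2)`` integer array of 0-based ``(x, y)`` grid positions, one per
        spectrum/row.  ``x`` indexes the grid column, ``y`` the grid row.
    mz_axis
        Length-``n`` non-decreasing vector of m/z bin centers.
    metadata
        Free-form provenance record.
    """

    values: sp.csr_matrix
    pixel_coords: np.ndarray
    mz_axis: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=np.int64)
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        m, n = self.values.shape
        if self.pixel_coords.shape != (m, 2):
            raise ValueError(
                f"pixel_coords must be ({m}, 2), got {self.pixel_coords.shape}"
            )
        if self.mz_axis.shape != (n,):
            raise ValueError(f"mz_axis must have length {n}, got {self.mz_axis.shape}")
        if np.any(np.diff(self.mz_axis) < 0):
            raise ValueError("mz_axis must be non-decreasing")
        if self.values.nnz:
            if not np.all(np.isfinite(self.values.data)):
                raise ValueError("intensities must be finite")
            if self.values.data.min() < 0:
                raise ValueError("intensities must be non-negative")
        coords = self.pixel_coords
        if len(np.unique(coords[:, 0] + 1j * coords[:, 1])) != m:
            raise ValueError("pixel_coords must be unique per row")

    # -- convenience constructors ------------------------------------------

    @classmethod
    def from_dense(
        cls,
        array: np.ndarray,
        pixel_coords: Optional[np.ndarray] = None,
        mz_axis: Optional[np.ndarray] = None,
        metadata: Optional[dict] = None,
    ) -> "SpectraMatrix":
        """Wrap a dense array; coordinates default to a row-major grid of width m."""
        array = np.asarray(array, dtype=np.float64)
        m, n = array.shape
        if pixel_coords is None:
            pixel_coords = np.column_stack([np.arange(m), np.zeros(m, dtype=np.int64)])
        if mz_axis is None:
            mz_axis = np.arange(n, dtype=np.float64)
        return cls(sp.csr_matrix(array), pixel_coords, mz_axis, metadata or {})

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def replace_values(self, values: sp.spmatrix) -> "SpectraMatrix":
        return SpectraMatrix(
            sp.csr_matrix(values), self.pixel_coords, self.mz_axis, dict(self.metadata)
        )


class ObservationMask:
    """The index set Omega of observed (sampled) matrix entries.

    Stored as parallel row/col index arrays in row-major sorted order; the
    complement Omega^c is the set of missing entries.  ``Omega`` and
    ``Omega^c`` always partition the full ``m x n`` index set.
    """

    def __init__(self, rows: np.ndarray, cols: np.ndarray, shape: tuple):
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        if rows.shape != cols.shape or rows.ndim != 1:
            raise ValueError("rows/cols must be equal-length 1-D arrays")
        m, n = shape
        if rows.size:
            if rows.min() < 0 or rows.max() >= m or cols.min() < 0 or cols.max() >= n:
                raise ValueError("mask indices out of bounds")
        lin = rows * n + cols
        order = np.argsort(lin, kind="stable")
        lin = lin[order]
        if lin.size and np.any(np.diff(lin) == 0):
            raise ValueError("duplicate indices in mask")
        self.rows = rows[order]
        self.cols = cols[order]
        self.shape = (int(m), int(n))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_nonzero(cls, matrix) -> "ObservationMask":
        """Omega = nonzero pattern of a (sparse) matrix.

        This is the default convention for clipped data: the instrument only
        reports values that survived the threshold, so stored entries are
        exactly the observed ones.
        """
        coo = sp.coo_matrix(matrix)
        return cls(coo.row, coo.col, coo.shape)

    @classmethod
    def full(cls, shape: tuple) -> "ObservationMask":
        m, n = shape
        rows = np.repeat(np.arange(m, dtype=np.int64), n)
        cols = np.tile(np.arange(n, dtype=np.int64), m)
        return cls(rows, cols, shape)

    @classmethod
    def empty(cls, shape: tuple) -> "ObservationMask":
        z = np.zeros(0, dtype=np.int64)
        return cls(z, z, shape)

    @classmethod
    def from_linear(cls, lin: np.ndarray, shape: tuple) -> "ObservationMask":
        lin = np.asarray(lin, dtype=np.int64)
        m, n = shape
        return cls(lin // n, lin % n, shape)

    # -- basic protocol -----------------------------------------------------

    def __len__(self) -> int:
        return self.rows.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ObservationMask)
            and self.shape == other.shape
            and np.array_equal(self.rows, other.rows)
            and np.array_equal(self.cols, other.cols)
        )

    @property
    def linear(self) -> np.ndarray:
        return self.rows * self.shape[1] + self.cols

    def complement(self) -> "ObservationMask":
        m, n = self.shape
        all_lin = np.arange(m * n, dtype=np.int64)
        keep = np.ones(m * n, dtype=bool)
        keep[self.linear] = False
        return ObservationMask.from_linear(all_lin[keep], self.shape)

    def to_bool_csr(self) -> sp.csr_matrix:
        data = np.ones(len(self), dtype=bool)
        return sp.csr_matrix((data, (self.rows, self.cols)), shape=self.shape)

    # -- projection helpers -------------------------------------------------

    def project(self, matrix) -> sp.csr_matrix:
        """Apply P_Omega to a dense or sparse matrix, returning CSR on Omega."""
        if matrix.shape != self.shape:
            raise ValueError(f"shape mismatch: {matrix.shape} vs {self.shape}")
        vals = self.extract(matrix)
        out = sp.csr_matrix((vals, (self.rows, self.cols)), shape=self.shape)
        return out

    def extract(self, matrix) -> np.ndarray:
        """Values of a dense/sparse matrix at Omega, in mask order."""
        if len(self) == 0:
            return np.zeros(0)
        if sp.issparse(matrix):
            csr = sp.csr_matrix(matrix)
            return np.asarray(csr[self.rows, self.cols], dtype=np.float64).ravel()
        return np.asarray(matrix)[self.rows, self.cols]

    def extract_factors(self, factors: "LowRankFactors", chunk: int = 1 << 20) -> np.ndarray:
        """Values of ``U diag(s) V^T`` at Omega without densifying the product."""
        out = np.empty(len(self), dtype=np.float64)
        Us = factors.left * factors.singvals  # m x r
        V = factors.right
        for start in range(0, len(self), chunk):
            stop = min(start + chunk, len(self))
            out[start:stop] = np.einsum(
                "ij,ij->i", Us[self.rows[start:stop]], V[self.cols[start:stop]]
            )
        return out

    def sparse_from_values(self, vals: np.ndarray) -> sp.csr_matrix:
        """Build the sparse matrix supported on Omega with the given values.

        The CSR ``data`` array is laid out exactly in mask (row-major) order,
        so solver code may update it in place against mask-ordered vectors.
        """
        vals = np.asarray(vals, dtype=np.float64)
        if vals.shape != self.rows.shape:
            raise ValueError("value vector length does not match |Omega|")
        m, _ = self.shape
        indptr = np.searchsorted(self.rows, np.arange(m + 1))
        return sp.csr_matrix((vals.copy(), self.cols.copy(), indptr), shape=self.shape)


@dataclass
class LowRankFactors:
    """Factored representation ``X = U diag(s) V^T`` of a low-rank matrix.

    ``left`` is ``m x r`` with orthonormal columns, ``singvals`` a
    non-increasing non-negative length-``r`` vector, ``right`` ``n x r`` with
    orthonormal columns.
    """

    left: np.ndarray
    singvals: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.atleast_2d(np.asarray(self.left, dtype=np.float64))
        self.right = np.atleast_2d(np.asarray(self.right, dtype=np.float64))
        self.singvals = np.atleast_1d(np.asarray(self.singvals, dtype=np.float64))
        r = self.singvals.size
        if self.left.shape[1] != r or self.right.shape[1] != r:
            raise ValueError("factor column counts must match singvals length")
        if np.any(self.singvals < 0):
            raise ValueError("singular values must be non-negative")
        if np.any(np.diff(self.singvals) > 1e-12 * max(1.0, abs(self.singvals[0]) if r else 1.0)):
            raise ValueError("singular values must be non-increasing")

    @property
    def rank(self) -> int:
        return int(self.singvals.size)

    @property
    def shape(self) -> tuple:
        return (self.left.shape[0], self.right.shape[0])

    @classmethod
    def zero(cls, shape: tuple) -> "LowRankFactors":
        m, n = shape
        return cls(np.zeros((m, 0)), np.zeros(0), np.zeros((n, 0)))

    def validate_orthonormal(self, tol: float = 1e-8) -> None:
        for mat, name in ((self.left, "left"), (self.right, "right")):
            if mat.shape[1] == 0:
                continue
            gram = mat.T @ mat
            if not np.allclose(gram, np.eye(mat.shape[1]), atol=tol):
                raise ValueError(f"{name} factor columns are not orthonormal")

    def dense(self) -> np.ndarray:
        return reconstruct(self)

    def frobenius_norm(self) -> float:
        return float(np.linalg.norm(self.singvals))

    def inner(self, other: "LowRankFactors") -> float:
        """Frobenius inner product <X, Y> computed through the small factors."""
        if self.rank == 0 or other.rank == 0:
            return 0.0
        C = (self.left * self.singvals).T @ (other.left * other.singvals)
        D = self.right.T @ other.right
        return float(np.sum(C * D))

    def frobenius_distance(self, other: "LowRankFactors") -> float:
        d2 = (
            self.frobenius_norm() ** 2
            + other.frobenius_norm() ** 2
            - 2.0 * self.inner(other)
        )
        return float(np.sqrt(max(d2, 0.0)))


@dataclass
class SolverConfig:
    """Hyperparameters shared by the SVT and FPC solvers.

    ``delta`` is the (dual/gradient) step size, ``tau`` the singular-value
    shrinkage threshold, ``sigma`` the noise-energy budget of the
    inequality-constrained program (FPC only).  ``delta=None`` / ``tau=None``
    request the canonical auto-rules (see the solver modules).
    """

    delta: Optional[float] = None
    tau: Optional[float] = None
    sigma: float = 0.0
    tol: float = 1e-4
    max_iter: int = 500
    svd_rank_increment: int = 10
    seed: int = 0
    dense_budget_gb: float = 1.0

    def __post_init__(self) -> None:
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 < self.tol < 1.0):
            raise ValueError("tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.svd_rank_increment < 1:
            raise ValueError("svd_rank_increment must be >= 1")


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def clip(M: SpectraMatrix, k: float) -> SpectraMatrix:
    """Acquisition-time intensity clipping: zero every entry below ``k``.

    Entries with intensity >= ``k`` are kept; the rest become implicit zeros
    and are dropped from sparse storage.  ``k=0`` is the identity (all stored
    intensities are non-negative).
    """
    if k < 0:
        raise ValueError("clip threshold k must be >= 0")
    out = M.values.copy().tocsr()
    if k > 0 and out.nnz:
        out.data[out.data < k] = 0.0
        out.eliminate_zeros()
    return M.replace_values(out)


def apply_mask(M: SpectraMatrix, mask: ObservationMask) -> SpectraMatrix:
    """Sampling operator P_Omega: keep entries in Omega, zero the rest."""
    if mask.shape != M.shape:
        raise ValueError(f"mask shape {mask.shape} does not match matrix {M.shape}")
    return M.replace_values(mask.project(M.values))


def _trimmed_tic(row_values: np.ndarray, low_pct: float, high_pct: float) -> float:
    lo, hi = np.percentile(row_values, [low_pct, high_pct])
    sel = row_values[(row_values >= lo) & (row_values <= hi)]
    return float(sel.sum())


def tic_normalize(
    M: SpectraMatrix, low_pct: float = 5.0, high_pct: float = 95.0
) -> SpectraMatrix:
    """Robust per-spectrum total-ion-current normalization (5–95%-TIC).

    Each spectrum (row) is divided by the sum of its nonzero intensities that
    fall between the row's ``low_pct`` and ``high_pct`` intensity percentiles
    (linear-interpolation percentiles).  This trims the extreme tails — base
    peaks and near-noise values — so that a handful of saturated peaks cannot
    dominate the scale.  All-zero rows and rows whose trimmed sum is zero are
    passed through unchanged with a warning.
    """
    out = M.values.copy().tocsr()
    degenerate = []
    for i in range(out.shape[0]):
        start, stop = out.indptr[i], out.indptr[i + 1]
        if start == stop:
            degenerate.append(i)
            continue
        row = out.data[start:stop]
        tic = _trimmed_tic(row, low_pct, high_pct)
        if tic <= 0:
            degenerate.append(i)
            continue
        out.data[start:stop] = row / tic
    if degenerate:
        warnings.warn(
            f"tic_normalize: {len(degenerate)} spectra with zero trimmed TIC "
            "left unscaled",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("tic_normalize skipped rows: %s", degenerate[:20])
    return M.replace_values(out)


def ion_image(M: SpectraMatrix, j: int) -> np.ndarray:
    """Rearrange column ``j`` onto the pixel grid as a 2-D ion image.

    The image covers the bounding box of ``pixel_coords``; grid positions not
    covered by any pixel are NaN (missing).
    """
    n = M.n_bins
    if not (0 <= j < n):
        raise IndexError(f"m/z-bin index {j} out of range [0, {n})")
    x = M.pixel_coords[:, 0]
    y = M.pixel_coords[:, 1]
    x0, y0 = x.min(), y.min()
    width = int(x.max() - x0 + 1)
    height = int(y.max() - y0 + 1)
    img = np.full((height, width), np.nan)
    col = np.asarray(M.values[:, j].todense()).ravel()
    img[y - y0, x - x0] = col
    return img


def reconstruct(
    F: LowRankFactors,
    rows: Optional[Sequence[int]] = None,
    cols: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Dense block ``U diag(s) V^T`` restricted to the requested rows/cols."""
    m, n = F.shape
    U = F.left
    V = F.right
    if rows is not None:
        rows = np.asarray(rows, dtype=np.int64)
        if rows.size and (rows.min() < 0 or rows.max() >= m):
            raise IndexError("row subset out of range")
        U = U[rows]
    if cols is not None:
        cols = np.asarray(cols, dtype=np.int64)
        if cols.size and (cols.min() < 0 or cols.max() >= n):
            raise IndexError("column subset out of range")
        V = V[cols]
    if F.rank == 0:
        return np.zeros((U.shape[0], V.shape[0]))
    return (U * F.singvals) @ V.T
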