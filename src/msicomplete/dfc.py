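"""Divide-factor-conquer (DFC) scaling wrapper for completion solvers.

DFC makes nuclear-norm completion tractable on matrices whose SVD cannot be
computed whole: (*divide*) the columns are split into ``t`` blocks,
(*factor*) the base solver — SVT or FPC — completes each block
independently, and (*conquer*) the block solutions are merged into a single
factorization by randomized projection: a Gaussian range-finder sketches the
column space of the concatenated block reconstructions, the blocks are
projected onto the resulting orthonormal basis, and a small SVD of the
projected matrix yields the final factors.

The conquer step is exact (up to floating point) whenever the sketch width
``sum of block ranks + oversampling`` covers the true combined rank, which
the property suite enforces against full solves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
import scipy.linalg

from .core import LowRankFactors, ObservationMask, SolverConfig, SpectraMatrix
from .solverlog import ConvergenceLog
from .svt import CompletionResult, svt_complete
from .fpc import fpc_complete

__all__ = ["ColumnPartition", "partition_columns", "dfc_complete"]


@dataclass
class ColumnPartition:
    """Disjoint column blocks covering ``0..n-1``."""

    blocks: List[np.ndarray]
    seed: int = 0

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=np.int64) for b in self.blocks]
        if any(b.size == 0 for b in self.blocks):
            raise ValueError("empty block in partition")
        allcols = np.concatenate(self.blocks)
        n = allcols.size
        if not np.array_equal(np.sort(allcols), np.arange(n)):
            raise ValueError("blocks must disjointly cover all columns")

    @property
    def n_columns(self) -> int:
        return sum(b.size for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def partition_columns(n: int, t: int, seed: int) -> ColumnPartition:
    """Shuffle columns by ``seed`` and split into ``t`` blocks of near-equal size."""
    if not (1 <= t <= n):
        raise ValueError(f"need 1 <= t <= n, got t={t}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    blocks = [np.sort(b) for b in np.array_split(perm, t)]
    return ColumnPartition(blocks, seed=seed)


def _submask(mask: ObservationMask, block: np.ndarray) -> ObservationMask:
    """Restrict a mask to a column block, re-indexing columns to 0..len(block)-1."""
    lut = -np.ones(mask.shape[1], dtype=np.int64)
    lut[block] = np.arange(block.size)
    newcols = lut[mask.cols]
    keep = newcols >= 0
    return ObservationMask(mask.rows[keep], newcols[keep], (mask.shape[0], block.size))


_BASE_SOLVERS: dict = {"svt": svt_complete, "fpc": fpc_complete}


def dfc_complete(
    M: SpectraMatrix,
    mask: ObservationMask,
    base: str = "svt",
    t: int = 1,
    cfg: Optional[SolverConfig] = None,
    partition: Optional[ColumnPartition] = None,
    rank_cap: Optional[int] = None,
    oversample: int = 10,
    base_solver: Optional[Callable] = None,
) -> CompletionResult:
    """Complete ``M`` blockwise and merge block factors by randomized projection.

    Parameters
    ----------
    base
        Name of the base solver, ``"svt"`` or ``"fpc"``.
    t
        Number of column blocks (ignored when ``partition`` is given).
    partition
        Explicit column partition; defaults to ``partition_columns(n, t, cfg.seed)``.
    rank_cap
        Optional truncation of the combined factorization.
    oversample
        Extra sketch columns beyond the summed block ranks.
    base_solver
        Custom ``(M, mask, cfg) -> CompletionResult`` callable overriding ``base``.
    """
    cfg = cfg or SolverConfig()
    if base_solver is None:
        if base not in _BASE_SOLVERS:
            raise ValueError(f"unknown base solver {base!r}")
        base_solver = _BASE_SOLVERS[base]
    m, n = M.shape
    if partition is None:
        partition = partition_columns(n, t, cfg.seed)
    if partition.n_columns != n:
        raise ValueError("partition does not cover the matrix columns")

    # -- divide + factor ----------------------------------------------------
    block_factors: List[LowRankFactors] = []
    logs: List[ConvergenceLog] = []
    for b_idx, block in enumerate(partition.blocks):
        sub_vals = M.values[:, block]
        sub = SpectraMatrix(
            sub_vals,
            M.pixel_coords,
            M.mz_axis[block],
            {**M.metadata, "dfc_block": b_idx},
        )
        sub_mask = _submask(mask, block)
        if len(sub_mask) == 0:
            raise ValueError(f"DFC block {b_idx} has an empty observation mask")
        try:
            res = base_solver(sub, sub_mask, cfg)
        except Exception as exc:
            raise RuntimeError(f"DFC block {b_idx} failed: {exc}") from exc
        block_factors.append(res.factors)
        logs.append(res.log)

    # -- conquer: randomized range finding over the block reconstructions ---
    total_rank = sum(f.rank for f in block_factors)
    combined_log = ConvergenceLog(method=f"dfc[{base}, t={partition.n_blocks}]")
    for lg in logs:
        combined_log.records.extend(lg.records)
    combined_log.converged = all(lg.converged for lg in logs)
    combined_log.stop_reason = "; ".join(lg.stop_reason for lg in logs)
    if total_rank == 0:
        return CompletionResult(LowRankFactors.zero(M.shape), combined_log)

    ell = min(total_rank + oversample, m, n)
    # per-block Gaussian sketches keyed by cfg.seed and block content order so
    # that identical blocks produce identical sketches regardless of context
    sketch = np.zeros((m, ell))
    for block, F in zip(partition.blocks, block_factors):
        rng = np.random.default_rng([cfg.seed, block.size, int(block[0])])
        G = rng.standard_normal((block.size, ell))
        if F.rank:
            sketch += F.left @ (F.singvals[:, None] * (F.right.T @ G))
    Q, _ = np.linalg.qr(sketch)

    # project each block onto the shared column span: B = Q^T X_block
    B = np.zeros((Q.shape[1], n))
    for block, F in zip(partition.blocks, block_factors):
        if F.rank:
            B[:, block] = (Q.T @ F.left) @ (F.singvals[:, None] * F.right.T)
    Ub, s, Vt = scipy.linalg.svd(B, full_matrices=False)

    keep = s > (1e-12 * s[0] if s.size else 0.0)
    if rank_cap is not None:
        keep &= np.arange(s.size) < rank_cap
    factors = LowRankFactors(Q @ Ub[:, keep], s[keep], Vt[keep].T)
    return CompletionResult(factors, combined_log)
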