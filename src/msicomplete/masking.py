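"""Sampling schemes that mimic acquisition-time missing-value mechanisms.

Two schemes are provided.  The *threshold* scheme (alpha) keeps the largest
intensity values, imitating instrument-side clipping where everything below a
relative ion count is discarded.  The *uniform* scheme (beta) keeps a random
subset of entries regardless of intensity, the sampling model under which
matrix-completion recovery guarantees are usually stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import ObservationMask, SpectraMatrix

__all__ = ["SamplingSpec", "mask_threshold", "mask_uniform", "build_mask"]


@dataclass
class SamplingSpec:
    """Declarative description of a sampling scheme."""

    scheme: Literal["threshold_alpha", "uniform_beta"]
    fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        if self.scheme not in ("threshold_alpha", "uniform_beta"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def _target_count(fraction: float, total: int) -> int:
    # round half away from zero, deterministic
    return int(np.floor(fraction * total + 0.5))


def mask_threshold(M: SpectraMatrix, fraction: float) -> ObservationMask:
    """Omega = positions of the top ``fraction`` of intensity values.

    All ``m*n`` entries (including implicit zeros) are candidates; zeros lose
    to any positive value.  Ties at the cutoff are broken by ascending
    (row, col) order, making the mask deterministic for a given matrix.
    """
    m, n = M.shape
    total = m * n
    if total == 0 or not (0.0 < fraction <= 1.0):
        raise ValueError("matrix must be non-empty and fraction in (0, 1]")
    q = _target_count(fraction, total)
    if q >= total:
        return ObservationMask.full(M.shape)

    coo = M.values.tocoo()
    data, rows, cols = coo.data, coo.row, coo.col
    pos = data > 0
    data, rows, cols = data[pos], rows[pos], cols[pos]
    lin = rows.astype(np.int64) * n + cols

    if q <= data.size:
        # sort by (-value, linear index): stable lexsort, last key primary
        order = np.lexsort((lin, -data))[:q]
        # all selected values are > 0 so zero entries never outrank them
        return ObservationMask.from_linear(lin[order], M.shape)

    # need every positive entry plus the first zero positions in (row, col) order
    zero_needed = q - data.size
    taken = np.zeros(total, dtype=bool)
    taken[lin] = True
    zero_lin = np.flatnonzero(~taken)[:zero_needed]
    return ObservationMask.from_linear(np.concatenate([lin, zero_lin]), M.shape)


def mask_uniform(M: SpectraMatrix, fraction: float, seed: int) -> ObservationMask:
    """Omega = ``round(fraction*m*n)`` entries drawn uniformly without replacement."""
    m, n = M.shape
    total = m * n
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    q = _target_count(fraction, total)
    if q >= total:
        return ObservationMask.full(M.shape)
    rng = np.random.default_rng(seed)
    lin = rng.choice(total, size=q, replace=False)
    return ObservationMask.from_linear(lin, M.shape)


def build_mask(M: SpectraMatrix, spec: SamplingSpec) -> ObservationMask:
    """Dispatch on a :class:`SamplingSpec`."""
    if spec.scheme == "threshold_alpha":
        return mask_threshold(M, spec.fraction)
    return mask_uniform(M, spec.fraction, spec.seed)
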