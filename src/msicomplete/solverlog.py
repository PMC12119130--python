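"""Structured per-iteration solver records for convergence inspection."""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from typing import List


@dataclass
class IterationRecord:
    iteration: int
    rank: int
    residual: float
    wall_time_s: float


@dataclass
class ConvergenceLog:
    """Iteration history of a completion solver run."""

    method: str
    records: List[IterationRecord] = field(default_factory=list)
    converged: bool = False
    stop_reason: str = ""
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    def append(self, iteration: int, rank: int, residual: float) -> None:
        self.records.append(
            IterationRecord(iteration, rank, residual, time.perf_counter() - self._t0)
        )

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    @property
    def final_residual(self) -> float:
        return self.records[-1].residual if self.records else float("nan")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "rank", "residual", "wall_time_s"])
            for rec in self.records:
                writer.writerow(
                    [rec.iteration, rec.rank, f"{rec.residual:.8e}", f"{rec.wall_time_s:.4f}"]
                )
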