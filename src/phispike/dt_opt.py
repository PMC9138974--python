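"""Lag (dt) selection by maximizing the mean per-neuron-normalized Phi."""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateSystemError, PhiSpikeError, RankDeficientError
from .selection import robust_phi
from .spike_data import BinnedMatrix

DEFAULT_GRID = tuple(range(1, 41))  # 0.03–1.2 s at the 0.03 s bin


@dataclass
class DtSweepResult:
    grid: tuple[int, ...]
    mean_phi: tuple[float, ...]          # nan where all sessions failed
    n_sessions_ok: tuple[int, ...]
    optimal_lag_bins: int
    optimal_lag_seconds: float
    warnings: tuple[str, ...] = ()

    def to_csv(self, path: str | os.PathLike) -> None:
        bin_size = self.optimal_lag_seconds / self.optimal_lag_bins
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["lag_bins", "lag_s", "mean_phi", "n_sessions_ok"])
            for lag, phi, ok in zip(self.grid, self.mean_phi, self.n_sessions_ok):
                writer.writerow([lag, repr(lag * bin_size),
                                 "" if np.isnan(phi) else repr(phi), ok])


def sweep_dt(sessions: Sequence[BinnedMatrix], method: str = "atomic",
             grid: Sequence[int] = DEFAULT_GRID, *, alpha: float = 0.05,
             seed: int = 0, cap: int = 15, top_k: int | None = None) -> DtSweepResult:
    """Mean normalized Phi per lag across sessions; argmax (ties -> smallest lag).

    Per-session Phi is the robust value divided by the number of neurons
    actually used.  A lag failing on every session is excluded from the
    argmax with a warning; if all lags fail the sweep errors out.
    """
    grid = tuple(int(g) for g in grid)
    if not grid or any(g < 1 for g in grid):
        raise ValueError("grid must be non-empty with all lags >= 1")
    if not sessions:
        raise ValueError("no sessions given")
    from .selection import select_top_k

    warnings: list[str] = []
    mean_phi: list[float] = []
    n_ok: list[int] = []
    for lag in grid:
        values = []
        for binned in sessions:
            work = select_top_k(binned, top_k) if top_k else binned
            try:
                result = robust_phi(work, method=method, lag_bins=lag,
                                    alpha=alpha, seed=seed, cap=cap)
            except (RankDeficientError, DegenerateSystemError, ValueError):
                continue
            values.append(result.phi / len(result.neurons_used))
        n_ok.append(len(values))
        if values:
            mean_phi.append(float(np.mean(values)))
        else:
            mean_phi.append(float("nan"))
            warnings.append(f"lag {lag}: failed on all sessions, excluded")
    finite = [i for i, v in enumerate(mean_phi) if not np.isnan(v)]
    if not finite:
        raise PhiSpikeError("dt sweep failed at every lag")
    best = max(finite, key=lambda i: (mean_phi[i], -grid[i]))
    bin_size = sessions[0].bin_size
    return DtSweepResult(grid=grid, mean_phi=tuple(mean_phi),
                         n_sessions_ok=tuple(n_ok),
                         optimal_lag_bins=grid[best],
                         optimal_lag_seconds=grid[best] * bin_size,
                         warnings=tuple(warnings))
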