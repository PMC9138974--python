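"""Session-level statistics: per-period Phi, reward rates, day averages,
and the Spearman/Bonferroni correlation between Phi and behavioral success.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSystemError, PhiSpikeError, RankDeficientError
from .selection import robust_phi, select_top_k
from .spike_data import BinnedMatrix, SessionData, binarize, split_periods

# method names: base partition method, optionally restricted to the top-15
# most variable neurons (the "15" suffix)
METHOD_VARIANTS = ("mib15", "atomic", "louvain", "atomic15", "louvain15")


@dataclass(frozen=True)
class PhiRunConfig:
    method: str = "mib15"
    bin_size: float = 0.03
    lag_bins: int = 1
    n_periods: int = 8
    alpha: float = 0.05
    seed: int = 0
    cap: int = 15
    top_k: int = 15
    reward_label: str = "reward"

    def base_method(self) -> str:
        return self.method[:-2] if self.method.endswith("15") else self.method

    def uses_top_k(self) -> bool:
        return self.method.endswith("15")


@dataclass
class PeriodRecord:
    session_id: str
    period_index: int
    phi_normalized: float | None
    n_neurons_used: int
    reward_rate: float
    duration_s: float
    day: str | None = None
    warnings: tuple[str, ...] = ()


@dataclass
class CorrelationReport:
    rho: float
    p_value: float
    n: int
    alpha_corrected: float
    significant: bool

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value, "n": self.n,
                "alpha_corrected": self.alpha_corrected,
                "significant": self.significant}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def stars(self, n_hypotheses: int = 1) -> str:
        """Star annotation: '**' below 0.01/h, '*' below 0.05/h, else 'ns'."""
        if self.p_value < bonferroni_alpha(0.01, n_hypotheses):
            return "**"
        if self.p_value < bonferroni_alpha(0.05, n_hypotheses):
            return "*"
        return "ns"


def period_phi(session: SessionData, config: PhiRunConfig,
               session_id: str = "session", day: str | None = None) -> list[PeriodRecord]:
    """Binarize, split into periods, compute robust Phi and reward rate per period.

    Phi is normalized by the number of neurons actually used.  A period
    where the computation fails entirely yields a record with missing phi
    (excluded downstream from correlations).
    """
    if config.method not in METHOD_VARIANTS and config.method not in ("mib",):
        raise ValueError(
            f"method must be one of {METHOD_VARIANTS}, got {config.method!r}")
    binned = binarize(session, config.bin_size)
    periods = split_periods(binned, config.n_periods)
    records: list[PeriodRecord] = []
    for idx, period in enumerate(periods):
        work = select_top_k(period, config.top_k) if config.uses_top_k() else period
        duration = period.duration_s
        lo = period.t_start
        rewards = len(session.events_in(lo, lo + duration, config.reward_label))
        rate = rewards / duration
        try:
            result = robust_phi(work, method=config.base_method(),
                                lag_bins=config.lag_bins, alpha=config.alpha,
                                seed=config.seed, cap=config.cap)
            n_used = len(result.neurons_used)
            records.append(PeriodRecord(
                session_id=session_id, period_index=idx,
                phi_normalized=result.phi / n_used, n_neurons_used=n_used,
                reward_rate=rate, duration_s=duration, day=day,
                warnings=result.warnings))
        except (RankDeficientError, DegenerateSystemError) as exc:
            records.append(PeriodRecord(
                session_id=session_id, period_index=idx, phi_normalized=None,
                n_neurons_used=0, reward_rate=rate, duration_s=duration,
                day=day, warnings=(f"period failed: {exc}",)))
    return records


def records_to_frame(records: Iterable[PeriodRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "session_id": r.session_id, "day": r.day, "period_index": r.period_index,
        "phi_normalized": r.phi_normalized, "n_neurons_used": r.n_neurons_used,
        "reward_rate": r.reward_rate, "duration_s": r.duration_s,
        "warnings": ";".join(r.warnings),
    } for r in records])


def day_average(records: Sequence[PeriodRecord]) -> pd.DataFrame:
    """Per-day, per-period mean of phi and reward rate across 1-2 sessions.

    Missing phi values are ignored in the mean; single-session days pass
    through unchanged.
    """
    frame = records_to_frame(records)
    if frame["day"].isna().any():
        raise ValueError("all records need a day label for day averaging")
    grouped = frame.groupby(["day", "period_index"], as_index=False).agg(
        phi_normalized=("phi_normalized", "mean"),
        reward_rate=("reward_rate", "mean"),
        n_sessions=("session_id", "nunique"),
    )
    return grouped


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Spearman rho (mid-rank ties) with a two-sided Student-t p-value.

    Pairs with a missing member are dropped; at least 4 complete pairs
    are required and constant inputs are rejected.
    """
    xv = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    yv = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    n = xv.size
    if n < 4:
        raise PhiSpikeError(f"need at least 4 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise PhiSpikeError("undefined correlation: constant input vector")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
        rho = math.copysign(1.0, rho)
    else:
        tval = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(tval), n - 2))
    return CorrelationReport(rho=rho, p_value=p, n=n,
                             alpha_corrected=math.nan, significant=False)


def bonferroni_alpha(alpha: float, n_hypotheses: int) -> float:
    """Per-test threshold alpha / n under Bonferroni correction."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_hypotheses < 1:
        raise ValueError("n_hypotheses must be >= 1")
    return alpha / n_hypotheses


def correlate_phi_rewards(records: Sequence[PeriodRecord],
                          n_hypotheses: int = 15,
                          family_alpha: float = 0.05) -> CorrelationReport:
    """Spearman correlation of per-period normalized Phi with reward rate,
    flagged against the Bonferroni-corrected threshold."""
    complete = [r for r in records if r.phi_normalized is not None]
    report = spearman_correlation(
        [r.phi_normalized for r in complete],
        [r.reward_rate for r in complete])
    threshold = bonferroni_alpha(family_alpha, n_hypotheses)
    report.alpha_corrected = threshold
    report.significant = report.p_value < threshold
    return report
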