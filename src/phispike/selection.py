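"""Bernoulli-variance neuron ranking and the rank-deficiency removal loop.

Neurons are ranked by p(1-p) where p is the fraction of "on" bins; the
variance is 0 for constant trains and peaks at 1/4 for balanced ones.
When a Phi computation fails on singular covariances, the single
lowest-variance neuron is dropped and the computation retried until a
value is obtained or fewer than two neurons remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateSystemError, RankDeficientError
from .phi_core import PhiResult, estimate_gaussian_model, phi_ar
from .spike_data import BinnedMatrix

METHODS = ("mib", "atomic", "louvain")


@dataclass(frozen=True)
class NeuronRank:
    neuron_id: str
    on_fraction: float
    bernoulli_variance: float


@dataclass(frozen=True)
class RemovalRecord:
    neuron_id: str
    bernoulli_variance: float
    attempt: int


def bernoulli_variance(binned_row: Sequence[int] | np.ndarray,
                       neuron_id: str = "") -> NeuronRank:
    """p(1-p) for a binary sequence with on-fraction p."""
    row = np.asarray(binned_row)
    if row.size == 0:
        raise ValueError("empty bin sequence")
    p = float(row.mean())
    return NeuronRank(neuron_id=neuron_id, on_fraction=p,
                      bernoulli_variance=p * (1.0 - p))


def rank_neurons(binned: BinnedMatrix) -> list[NeuronRank]:
    return [bernoulli_variance(binned.states[i], binned.neuron_ids[i])
            for i in range(binned.n_neurons)]


def select_top_k(binned: BinnedMatrix, k: int) -> BinnedMatrix:
    """Keep the k most variable neurons, preserving original row order.

    Ties at the cutoff go to the lower original index.  If fewer than k
    neurons exist the input is returned unchanged.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if binned.n_neurons <= k:
        return binned
    variances = np.array([r.bernoulli_variance for r in rank_neurons(binned)])
    # stable argsort descending: ties keep original index order
    order = np.argsort(-variances, kind="stable")
    keep = sorted(order[:k].tolist())
    return binned.subset_rows(keep)


def _partition_for(binned: BinnedMatrix, method: str, *, alpha: float,
                   seed: int, cap: int, lag_bins: int, normalize: bool) -> PhiResult:
    from .connectivity import louvain_partition
    from .partitions import atomic_partition, mib_search

    model = estimate_gaussian_model(binned, lag_bins)
    if method == "mib":
        return mib_search(model, normalize=normalize, cap=cap)
    if method == "atomic":
        return phi_ar(model, atomic_partition(binned.n_neurons), normalize=normalize)
    if method == "louvain":
        partition, warns = louvain_partition(binned, alpha=alpha, seed=seed)
        result = phi_ar(model, partition, normalize=normalize)
        result.warnings = result.warnings + warns
        return result
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def robust_phi(binned: BinnedMatrix, method: str = "mib", lag_bins: int = 1,
               *, alpha: float = 0.05, seed: int = 0, cap: int = 15,
               normalize: bool = True,
               removal_log: list[RemovalRecord] | None = None) -> PhiResult:
    """Phi with iterative removal of the lowest-variance neuron on failure.

    Removal ties are broken by original row index; the removal history is
    appended to ``removal_log`` when provided and summarized in the
    result's warnings.
    """
    current = binned
    attempt = 0
    removed: list[RemovalRecord] = []
    while current.n_neurons >= 2:
        try:
            result = _partition_for(current, method, alpha=alpha, seed=seed,
                                    cap=cap, lag_bins=lag_bins, normalize=normalize)
        except RankDeficientError:
            ranks = rank_neurons(current)
            variances = np.array([r.bernoulli_variance for r in ranks])
            worst = int(np.argmin(variances))  # argmin takes lowest index on ties
            record = RemovalRecord(neuron_id=current.neuron_ids[worst],
                                   bernoulli_variance=float(variances[worst]),
                                   attempt=attempt)
            removed.append(record)
            if removal_log is not None:
                removal_log.append(record)
            keep = [i for i in range(current.n_neurons) if i != worst]
            current = current.subset_rows(keep)
            attempt += 1
            continue
        if removed:
            result.warnings = result.warnings + (
                f"removed {len(removed)} low-variance neurons: "
                + ",".join(r.neuron_id for r in removed),)
        return result
    raise DegenerateSystemError(
        f"system degenerate: {attempt} removals left fewer than 2 usable neurons")
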