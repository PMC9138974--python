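"""Autoregressive integrated information from second-order statistics.

The central quantity compares how well the whole system's future is
linearly predictable from its own past against the same predictability
computed part-by-part for a partition of the neurons:

    phi_raw = 1/2 ln[det S(X) / det S(E_X)]
              - sum_k 1/2 ln[det S(M_k) / det S(E_{M_k})]

where ``S(.)`` is an equal-time covariance and ``S(E_.)`` the residual
covariance of the least-squares linear prediction of the future state
from the past state at a fixed lag.  The normalized value divides by

    L = 1/2 ln[ min_k (2*pi*e)^{|M_k|} det S(M_k) ]

which damps the dependence on unequal part sizes.  Natural logarithms
throughout.  A small-system discrete-entropy estimator over empirical
state distributions is provided as an independent cross-check.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import RankDeficientError
from .spike_data import BinnedMatrix

COND_LIMIT = 1e12
NORMALIZATION_EPS = 1e-9


@dataclass(frozen=True)
class Partition:
    """Disjoint non-empty index subsets covering 0..N-1."""

    subsets: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        subs = tuple(tuple(sorted(int(i) for i in s)) for s in self.subsets)
        object.__setattr__(self, "subsets", subs)
        if not subs or any(len(s) == 0 for s in subs):
            raise ValueError("every subset must be non-empty")
        flat = [i for s in subs for i in s]
        if len(flat) != len(set(flat)):
            raise ValueError("subsets must be pairwise disjoint")
        if set(flat) != set(range(len(flat))):
            raise ValueError("subsets must cover 0..N-1 exactly")

    @property
    def r(self) -> int:
        return len(self.subsets)

    @property
    def n(self) -> int:
        return sum(len(s) for s in self.subsets)

    def relabel(self, perm: Sequence[int]) -> "Partition":
        """Partition of the permuted system: index i -> perm[i]."""
        return Partition(tuple(tuple(perm[i] for i in s) for s in self.subsets))

    def as_labels(self, neuron_ids: Sequence[str]) -> list[list[str]]:
        return [[neuron_ids[i] for i in s] for s in self.subsets]


@dataclass
class GaussianModel:
    """Equal-time and lagged covariances of the binned state vectors."""

    cov0: np.ndarray
    covlag: np.ndarray
    lag_bins: int
    n_samples: int
    neuron_ids: tuple[str, ...]
    degenerate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.cov0 = np.asarray(self.cov0, dtype=float)
        self.covlag = np.asarray(self.covlag, dtype=float)
        n = self.cov0.shape[0]
        if self.cov0.shape != (n, n) or self.covlag.shape != (n, n):
            raise ValueError("cov0 and covlag must be square and congruent")
        if not np.allclose(self.cov0, self.cov0.T, atol=1e-10):
            raise ValueError("cov0 must be symmetric")
        if self.lag_bins < 1:
            raise ValueError("lag_bins must be >= 1")
        self.neuron_ids = tuple(self.neuron_ids)
        if len(self.neuron_ids) != n:
            raise ValueError("neuron_ids length mismatch")

    @property
    def n(self) -> int:
        return self.cov0.shape[0]


@dataclass
class PhiResult:
    phi: float
    phi_raw: float
    normalization: float
    partition: Partition
    neurons_used: tuple[str, ...]
    lag_bins: int
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "phi": self.phi,
            "phi_raw": self.phi_raw,
            "normalization": self.normalization,
            "lag_bins": self.lag_bins,
            "partition": [[self.neurons_used[i] for i in s]
                          for s in self.partition.subsets],
            "neurons_used": list(self.neurons_used),
            "warnings": list(self.warnings),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def estimate_gaussian_model_array(x: np.ndarray, lag_bins: int,
                                  neuron_ids: Sequence[str] | None = None) -> GaussianModel:
    """Second-order model from an arbitrary real-valued N x T array.

    Past samples are columns ``0..T-lag-1``, future samples the columns
    shifted by ``lag_bins``; means are removed per neuron separately for
    the past and future windows (unbiased ``n-1`` denominator).
    """
    if lag_bins < 1:
        raise ValueError("lag_bins must be >= 1")
    x = np.asarray(x, dtype=float)
    n, t = x.shape
    if neuron_ids is None:
        neuron_ids = tuple(str(i) for i in range(n))
    if t < lag_bins + n + 2:
        raise ValueError(
            f"need at least lag_bins + N + 2 = {lag_bins + n + 2} bins, got {t}")
    past = x[:, : t - lag_bins]
    fut = x[:, lag_bins:]
    n_samples = t - lag_bins
    past_c = past - past.mean(axis=1, keepdims=True)
    fut_c = fut - fut.mean(axis=1, keepdims=True)
    denom = n_samples - 1
    cov0 = past_c @ past_c.T / denom
    covlag = past_c @ fut_c.T / denom
    cov0 = (cov0 + cov0.T) / 2.0
    degenerate = tuple(
        neuron_ids[i] for i in range(n) if cov0[i, i] <= 0.0
    )
    return GaussianModel(cov0=cov0, covlag=covlag, lag_bins=lag_bins,
                         n_samples=n_samples, neuron_ids=tuple(neuron_ids),
                         degenerate=degenerate)


def estimate_gaussian_model(binned: BinnedMatrix, lag_bins: int) -> GaussianModel:
    """Sample second-order model of a binned binary state matrix."""
    return estimate_gaussian_model_array(
        binned.states.astype(float), lag_bins, binned.neuron_ids)


def _logdet_checked(mat: np.ndarray, what: str) -> float:
    """log-determinant via pivoted factorization; raises on rank deficiency."""
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0 or not np.isfinite(logdet):
        raise RankDeficientError(f"{what}: non-positive determinant")
    if np.linalg.cond(mat) > COND_LIMIT:
        raise RankDeficientError(f"{what}: condition number exceeds {COND_LIMIT:g}")
    return float(logdet)


def residual_covariance(model: GaussianModel, subset: Sequence[int]) -> np.ndarray:
    """Residual covariance of the subset's self-prediction.

    With S00 the subset block of cov0 and S01 the subset block of covlag,
    returns ``S00 - S01.T @ inv(S00) @ S01`` (prediction of the subset's
    future from the subset's own past only).
    """
    idx = np.asarray(sorted(subset), dtype=int)
    if idx.size == 0:
        raise ValueError("subset must be non-empty")
    s00 = model.cov0[np.ix_(idx, idx)]
    s01 = model.covlag[np.ix_(idx, idx)]
    _logdet_checked(s00, f"cov0 subset {idx.tolist()}")
    solved = np.linalg.solve(s00, s01)
    resid = s00 - s01.T @ solved
    return (resid + resid.T) / 2.0


def _subset_term(model: GaussianModel, subset: Sequence[int]) -> tuple[float, float]:
    """(1/2 ln det S00 - 1/2 ln det S(E), logdet S00) for one subset."""
    idx = list(sorted(subset))
    s00 = model.cov0[np.ix_(idx, idx)]
    logdet_s00 = _logdet_checked(s00, f"cov0 subset {idx}")
    resid = residual_covariance(model, idx)
    logdet_resid = _logdet_checked(resid, f"residual subset {idx}")
    return 0.5 * (logdet_s00 - logdet_resid), logdet_s00


def phi_ar(model: GaussianModel, partition: Partition,
           normalize: bool = True) -> PhiResult:
    """Integrated information of ``model`` under ``partition``.

    ``r = 1`` returns 0 by definition.  When the normalization factor is
    not safely positive the raw value is returned with a warning flag.
    """
    if partition.n != model.n:
        raise ValueError("partition size does not match model size")
    warnings: list[str] = []
    if partition.r == 1:
        return PhiResult(phi=0.0, phi_raw=0.0, normalization=0.0,
                         partition=partition, neurons_used=model.neuron_ids,
                         lag_bins=model.lag_bins,
                         warnings=("single-subset partition: phi is 0",))
    whole_term, _ = _subset_term(model, range(model.n))
    part_terms = []
    logdets = []
    sizes = []
    for sub in partition.subsets:
        term, logdet = _subset_term(model, sub)
        part_terms.append(term)
        logdets.append(logdet)
        sizes.append(len(sub))
    phi_raw = whole_term - sum(part_terms)
    log2pe = math.log(2.0 * math.pi * math.e)
    normalization = 0.5 * min(
        size * log2pe + logdet for size, logdet in zip(sizes, logdets)
    )
    if normalize and normalization > NORMALIZATION_EPS:
        phi = phi_raw / normalization
    else:
        phi = phi_raw
        if normalize:
            warnings.append(
                f"normalization {normalization:.3g} <= eps; returning raw value")
    if not math.isfinite(phi_raw):
        raise RankDeficientError("non-finite phi value")
    return PhiResult(phi=phi, phi_raw=phi_raw, normalization=normalization,
                     partition=partition, neurons_used=model.neuron_ids,
                     lag_bins=model.lag_bins, warnings=tuple(warnings))


def phi_discrete(binned: BinnedMatrix, lag_bins: int, partition: Partition) -> float:
    """Discrete-entropy estimator for tiny binary systems (N <= 10).

    Plug-in conditional entropies (nats) from the empirical joint
    distribution of (X_t, X_{t+lag}):

        sum_k H(M_{t,k} | M_{t+lag,k}) - H(X_t | X_{t+lag})
    """
    n = binned.n_neurons
    if n > 10:
        raise ValueError("oracle restricted to small systems (N <= 10)")
    if partition.n != n:
        raise ValueError("partition size mismatch")
    if partition.r == 1:
        return 0.0
    t = binned.n_bins
    if t <= lag_bins:
        raise ValueError("not enough bins for the requested lag")
    past = binned.states[:, : t - lag_bins]
    fut = binned.states[:, lag_bins:]

    def cond_entropy(rows: Sequence[int]) -> float:
        rows = list(rows)
        joint = Counter(
            (tuple(past[rows, j]), tuple(fut[rows, j]))
            for j in range(past.shape[1])
        )
        future: Counter = Counter()
        for (_, f), c in joint.items():
            future[f] += c
        total = past.shape[1]
        h_joint = -sum((c / total) * math.log(c / total) for c in joint.values())
        h_future = -sum((c / total) * math.log(c / total) for c in future.values())
        return h_joint - h_future

    whole = cond_entropy(range(n))
    return sum(cond_entropy(s) for s in partition.subsets) - whole
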