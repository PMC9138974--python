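"""Significance-thresholded spike-correlation graphs and Louvain communities.

The connectivity matrix holds |Pearson r| between pairs of binary bin
sequences wherever the zero-correlation null is rejected (two-sided
t-test, bins-2 d.f.), and exactly zero elsewhere.  Community detection
is a from-scratch two-phase Louvain maximizing the weighted modularity

    M = 1/(2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j)

with m = half the total weight, k_i the weighted degree.  Local moves
use the incremental gain of inserting an isolated node into a community

    dM = [(S_in + 2 k_i,in)/2m - ((S_tot + k_i)/2m)^2]
         - [S_in/2m - (S_tot/2m)^2 - (k_i/2m)^2]

followed by aggregation of communities into super-nodes, repeated until
no move improves modularity.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import PhiSpikeError
from .phi_core import Partition
from .spike_data import BinnedMatrix

_GAIN_EPS = 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric non-negative weight matrix with zero diagonal."""

    weights: np.ndarray
    alpha: float
    neuron_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self.neuron_ids = tuple(self.neuron_ids)
        if len(self.neuron_ids) != w.shape[0]:
            raise ValueError("neuron_ids length mismatch")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        """m: each undirected edge counted once."""
        return float(self.weights.sum()) / 2.0

    def to_edge_list_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["i", "j", "weight"])
            for i in range(self.n):
                for j in range(i + 1, self.n):
                    if self.weights[i, j] != 0.0:
                        writer.writerow([self.neuron_ids[i], self.neuron_ids[j],
                                         repr(self.weights[i, j])])

    def to_dense_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["neuron_id", *self.neuron_ids])
            for nid, row in zip(self.neuron_ids, self.weights):
                writer.writerow([nid, *[repr(v) for v in row]])


@dataclass
class CommunityAssignment:
    """Node -> community mapping (ids contiguous from 0) with its modularity."""

    community_of: tuple[int, ...]
    modularity: float

    @property
    def n_communities(self) -> int:
        return max(self.community_of) + 1 if self.community_of else 0

    def members(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_communities)]
        for node, c in enumerate(self.community_of):
            out[c].append(node)
        return out


def connectivity_matrix(binned: BinnedMatrix, alpha: float = 0.05,
                        method: str = "pearson") -> ConnectivityMatrix:
    """Pairwise zero-lag correlation of binary bin sequences, thresholded.

    A_ij = |r_ij| when the two-sided p-value (t transform, bins-2 d.f.)
    is below ``alpha``, else 0.  Constant neurons yield all-zero rows.
    """
    if binned.n_neurons < 2:
        raise PhiSpikeError("connectivity needs at least 2 neurons")
    if binned.n_bins < 10:
        raise PhiSpikeError("connectivity needs at least 10 bins")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    x = binned.states.astype(float)
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    n, t = x.shape
    sd = x.std(axis=1)
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    r = np.clip(r, -1.0, 1.0)
    df = t - 2
    with np.errstate(divide="ignore", over="ignore"):
        # |r| == 1 overflows to +-inf, which the t sf maps to p = 0
        tval = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    weights = np.where(pval < alpha, np.abs(r), 0.0)
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2.0
    return ConnectivityMatrix(weights=weights, alpha=alpha,
                              neuron_ids=binned.neuron_ids)


def modularity(A: ConnectivityMatrix, communities: CommunityAssignment | Sequence[int]) -> float:
    """Weighted Newman modularity of an assignment on A."""
    labels = (communities.community_of
              if isinstance(communities, CommunityAssignment) else tuple(communities))
    if len(labels) != A.n:
        raise ValueError("assignment length mismatch")
    m = A.total_weight
    if m <= 0:
        raise PhiSpikeError("empty graph: modularity undefined")
    w = A.weights
    k = w.sum(axis=1)
    labels_arr = np.asarray(labels)
    same = labels_arr[:, None] == labels_arr[None, :]
    return float(((w - np.outer(k, k) / (2.0 * m)) * same).sum() / (2.0 * m))


def _local_moves(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Louvain phase 1 on dense weights (may contain self-loops); returns labels."""
    n = w.shape[0]
    k = w.sum(axis=1)  # includes self-loop weight (counted as w[i,i])
    two_m = k.sum()
    labels = np.arange(n)
    # sigma_tot per community: sum of degrees of member nodes
    sigma_tot = k.copy().astype(float)
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for i in order:
            ci = labels[i]
            ki = k[i]
            # weights from i to each community (excluding self-loop)
            neigh = np.nonzero(w[i])[0]
            links: dict[int, float] = {}
            for j in neigh:
                if j == i:
                    continue
                links[labels[j]] = links.get(labels[j], 0.0) + w[i, j]
            # remove i from its community
            sigma_tot[ci] -= ki
            k_i_old = links.get(ci, 0.0)
            best_c, best_gain = ci, 0.0
            for c, k_i_in in links.items():
                # gain relative to staying isolated; constant terms cancel
                gain = k_i_in - sigma_tot[c] * ki / two_m
                ref = k_i_old - sigma_tot[ci] * ki / two_m
                delta = gain - ref
                if delta > best_gain + _GAIN_EPS:
                    best_gain = delta
                    best_c = c
            labels[i] = best_c
            sigma_tot[best_c] += ki
            if best_c != ci:
                improved = True
    return labels


def _aggregate(w: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse communities into super-nodes; returns (new weights, relabel map)."""
    uniq, compact = np.unique(labels, return_inverse=True)
    nc = uniq.size
    agg = np.zeros((nc, nc))
    for a in range(w.shape[0]):
        for b in range(w.shape[0]):
            agg[compact[a], compact[b]] += w[a, b]
    return agg, compact


def louvain(A: ConnectivityMatrix, seed: int = 0) -> CommunityAssignment:
    """Two-phase Louvain modularity maximization (seeded node order)."""
    m = A.total_weight
    if m <= 0:
        raise PhiSpikeError("empty graph: no edges to cluster")
    rng = np.random.default_rng(seed)
    w = A.weights.copy()
    node_to_comm = np.arange(A.n)  # flat assignment on original nodes
    while True:
        labels = _local_moves(w, rng)
        agg, compact = _aggregate(w, labels)
        node_to_comm = compact[node_to_comm]
        if agg.shape[0] == w.shape[0]:
            break
        w = agg
    # compact ids in first-appearance order for determinism
    _, flat = np.unique(node_to_comm, return_inverse=True)
    remap: dict[int, int] = {}
    final = []
    for c in flat:
        if c not in remap:
            remap[c] = len(remap)
        final.append(remap[c])
    q = modularity(A, final)
    return CommunityAssignment(community_of=tuple(int(c) for c in final),
                               modularity=q)


def louvain_partition(binned: BinnedMatrix, alpha: float = 0.05,
                      seed: int = 0) -> tuple[Partition, tuple[str, ...]]:
    """Community partition of the neurons; falls back to atomic when degenerate.

    Returns (partition, warnings).  Zero-degree nodes become their own
    singleton subsets; an all-singleton or single-community outcome falls
    back to the atomic partition with a warning.
    """
    from .partitions import atomic_partition

    warnings: list[str] = []
    A = connectivity_matrix(binned, alpha=alpha)
    if A.total_weight <= 0:
        return atomic_partition(binned.n_neurons), (
            "no significant edges: using atomic partition",)
    degrees = A.weights.sum(axis=1)
    connected = np.nonzero(degrees > 0)[0]
    isolated = np.nonzero(degrees == 0)[0]
    sub = ConnectivityMatrix(
        weights=A.weights[np.ix_(connected, connected)], alpha=alpha,
        neuron_ids=tuple(A.neuron_ids[i] for i in connected))
    assignment = louvain(sub, seed=seed)
    subsets = [tuple(int(connected[i]) for i in members)
               for members in assignment.members()]
    subsets.extend((int(i),) for i in isolated)
    partition = Partition(tuple(subsets))
    if partition.r == 1:
        warnings.append("single community found: using atomic partition")
        return atomic_partition(binned.n_neurons), tuple(warnings)
    return partition, tuple(warnings)
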