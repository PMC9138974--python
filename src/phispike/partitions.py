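"""Partition combinatorics and the brute-force minimum-information bipartition."""

from __future__ import annotations

from typing import Iterator

from .errors import RankDeficientError
from .phi_core import GaussianModel, Partition, PhiResult, phi_ar

DEFAULT_ENUMERATION_CAP = 15


def count_bipartitions(n: int) -> int:
    """Number of unordered two-part set partitions: 2^(n-1) - 1."""
    if n < 2:
        raise ValueError("bipartitions need n >= 2")
    return 2 ** (n - 1) - 1


def bell_number(n: int) -> int:
    """Total count of set partitions via the Bell-triangle recurrence."""
    if n < 0:
        raise ValueError("n must be non-negative")
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for value in row:
            nxt.append(nxt[-1] + value)
        row = nxt
    return row[0]


def enumerate_bipartitions(n: int, cap: int = DEFAULT_ENUMERATION_CAP) -> Iterator[Partition]:
    """Yield each unordered bipartition of {0..n-1} exactly once.

    Canonical form: the subset containing index 0 comes first; ordering is
    by size of the first subset, then lexicographic within a size.
    """
    if n < 2:
        raise ValueError("bipartitions need n >= 2")
    if n > cap:
        raise ValueError(
            f"n={n} exceeds enumeration cap {cap}; use an approximate partition")
    from itertools import combinations

    rest = list(range(1, n))
    for size in range(1, n):
        # first subset has `size` members and always contains index 0
        for extra in combinations(rest, size - 1):
            first = (0, *extra)
            second = tuple(i for i in rest if i not in set(extra))
            if not second:
                continue
            yield Partition((first, second))


def atomic_partition(n: int) -> Partition:
    """Every index in its own singleton subset."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return Partition(tuple((i,) for i in range(n)))


def mib_search(model: GaussianModel, normalize: bool = True,
               cap: int = DEFAULT_ENUMERATION_CAP) -> PhiResult:
    """Exhaustive minimum-information-bipartition search.

    Returns the bipartition minimizing the (normalized, unless disabled)
    phi value; ties broken by canonical enumeration order.  Bipartitions
    that fail numerically are skipped and counted; if every candidate
    fails the rank-deficiency propagates to the caller.
    """
    best: PhiResult | None = None
    n_failed = 0
    for partition in enumerate_bipartitions(model.n, cap=cap):
        try:
            result = phi_ar(model, partition, normalize=normalize)
        except RankDeficientError:
            n_failed += 1
            continue
        if best is None or result.phi < best.phi:
            best = result
    if best is None:
        raise RankDeficientError(
            f"all {count_bipartitions(model.n)} bipartitions rank-deficient")
    if n_failed:
        best.warnings = best.warnings + (
            f"{n_failed} bipartitions skipped as rank-deficient",)
    return best
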