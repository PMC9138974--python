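"""Spike/event tables, binarization into binary state matrices, period splits.

Spike data is held as per-neuron sorted spike-time arrays.  Binarization
maps a session onto a dense ``neurons x bins`` {0,1} matrix with
half-open bins ``[t_start + i*bin, t_start + (i+1)*bin)``; a trailing
partial bin is discarded.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InputFormatError, PhiSpikeError

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) of one neuron."""

    neuron_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size and not np.all(np.isfinite(times)):
            raise ValueError(f"non-finite spike time for neuron {self.neuron_id!r}")
        if times.size and times.min() < 0:
            raise ValueError(f"negative spike time for neuron {self.neuron_id!r}")
        times = np.sort(times)
        if times.size > 1 and np.min(np.diff(times)) <= _TIME_TOL:
            times = _dedupe(times)
        object.__setattr__(self, "spike_times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def _dedupe(sorted_times: np.ndarray) -> np.ndarray:
    keep = np.ones(sorted_times.size, dtype=bool)
    keep[1:] = np.diff(sorted_times) > _TIME_TOL
    return sorted_times[keep]


@dataclass(frozen=True)
class SessionData:
    """A recording session: spike trains, behavioral events, time bounds."""

    trains: tuple[SpikeTrain, ...]
    events: tuple[tuple[float, str], ...] = ()
    t_start: float = 0.0
    t_end: float | None = None

    def __post_init__(self) -> None:
        trains = tuple(self.trains)
        object.__setattr__(self, "trains", trains)
        object.__setattr__(self, "events", tuple(self.events))
        t_end = self.t_end
        if t_end is None:
            last_spike = max((t.spike_times[-1] for t in trains if t.n_spikes), default=0.0)
            last_event = max((t for t, _ in self.events), default=0.0)
            t_end = float(max(last_spike, last_event))
            object.__setattr__(self, "t_end", t_end)
        if not t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def neuron_ids(self) -> tuple[str, ...]:
        return tuple(t.neuron_id for t in self.trains)

    @property
    def duration_s(self) -> float:
        return float(self.t_end - self.t_start)

    def events_in(self, lo: float, hi: float, label: str | None = None) -> list[tuple[float, str]]:
        """Events with time in the half-open window [lo, hi)."""
        return [
            (t, lab)
            for t, lab in self.events
            if lo <= t < hi and (label is None or lab == label)
        ]


@dataclass
class BinnedMatrix:
    """Binary neuron-by-bin state matrix."""

    states: np.ndarray
    bin_size: float
    neuron_ids: tuple[str, ...]
    t_start: float = 0.0

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.ndim != 2:
            raise ValueError("states must be 2-D (neurons x bins)")
        if states.size and not np.isin(states, (0, 1)).all():
            raise ValueError("states entries must be 0 or 1")
        self.states = states.astype(np.int8, copy=False)
        self.neuron_ids = tuple(self.neuron_ids)
        if len(self.neuron_ids) != states.shape[0]:
            raise ValueError("neuron_ids length must match row count")

    @property
    def n_neurons(self) -> int:
        return self.states.shape[0]

    @property
    def n_bins(self) -> int:
        return self.states.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_size

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_s

    def subset_rows(self, rows: Sequence[int]) -> "BinnedMatrix":
        rows = list(rows)
        return BinnedMatrix(
            states=self.states[rows, :],
            bin_size=self.bin_size,
            neuron_ids=tuple(self.neuron_ids[i] for i in rows),
            t_start=self.t_start,
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        """Dense CSV dump: one row per neuron, first column the id."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["neuron_id"] + [f"bin{i}" for i in range(self.n_bins)])
            for nid, row in zip(self.neuron_ids, self.states):
                writer.writerow([nid] + row.tolist())


def load_spike_table(path: str | os.PathLike, format: str = "long_csv",
                     events_path: str | os.PathLike | None = None,
                     t_start: float = 0.0,
                     t_end: float | None = None) -> SessionData:
    """Load spikes (and optional events) into a :class:`SessionData`.

    ``long_csv``: header ``neuron_id,time_s``, one spike per row.
    ``per_neuron_dir``: a directory of whitespace-separated time lists,
    one file per neuron, filename = neuron id.
    """
    if format == "long_csv":
        spikes = _read_long_csv(path)
    elif format == "per_neuron_dir":
        spikes = _read_per_neuron_dir(path)
    else:
        raise ValueError(f"unknown spike table format {format!r}")
    if not spikes:
        raise InputFormatError(f"no spikes in {path}")
    trains = tuple(
        SpikeTrain(neuron_id=nid, spike_times=np.asarray(times, dtype=float))
        for nid, times in sorted(spikes.items())
    )
    events: tuple[tuple[float, str], ...] = ()
    if events_path is not None:
        events = tuple(_read_event_csv(events_path))
    return SessionData(trains=trains, events=events, t_start=t_start, t_end=t_end)


def _read_long_csv(path: str | os.PathLike) -> dict[str, list[float]]:
    spikes: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise InputFormatError(f"empty file: {path}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise InputFormatError(f"{path}:{lineno}: expected 'neuron_id,time_s'")
            nid = row[0].strip()
            try:
                t = float(row[1])
            except ValueError as exc:
                raise InputFormatError(f"{path}:{lineno}: unparseable time {row[1]!r}") from exc
            if not np.isfinite(t) or t < 0:
                raise InputFormatError(f"{path}:{lineno}: invalid time {t}")
            spikes.setdefault(nid, []).append(t)
    return spikes


def _read_per_neuron_dir(path: str | os.PathLike) -> dict[str, list[float]]:
    spikes: dict[str, list[float]] = {}
    for name in sorted(os.listdir(path)):
        full = os.path.join(path, name)
        if not os.path.isfile(full):
            continue
        nid = os.path.splitext(name)[0]
        with open(full) as fh:
            tokens = fh.read().split()
        times = []
        for tok in tokens:
            try:
                t = float(tok)
            except ValueError as exc:
                raise InputFormatError(f"{full}: unparseable time {tok!r}") from exc
            if not np.isfinite(t) or t < 0:
                raise InputFormatError(f"{full}: invalid time {t}")
            times.append(t)
        spikes[nid] = times
    return spikes


def _read_event_csv(path: str | os.PathLike) -> list[tuple[float, str]]:
    events: list[tuple[float, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader, None)  # header "time_s,label"
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise InputFormatError(f"{path}:{lineno}: expected 'time_s,label'")
            try:
                t = float(row[0])
            except ValueError as exc:
                raise InputFormatError(f"{path}:{lineno}: unparseable time {row[0]!r}") from exc
            events.append((t, row[1].strip()))
    events.sort(key=lambda e: e[0])
    return events


def write_spike_csv(session: SessionData, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["neuron_id", "time_s"])
        for train in session.trains:
            for t in train.spike_times:
                writer.writerow([train.neuron_id, repr(float(t))])


def write_event_csv(session: SessionData, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "label"])
        for t, label in session.events:
            writer.writerow([repr(float(t)), label])


def binarize(session: SessionData, bin_size: float = 0.03) -> BinnedMatrix:
    """Convert spike times to an on/off matrix (saturating: >=1 spike -> 1).

    Bin ``i`` covers ``[t_start + i*bin_size, t_start + (i+1)*bin_size)``;
    the trailing partial bin (and any spike at exactly ``t_end``) is dropped.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not session.trains:
        raise ValueError("session has no spike trains")
    n_bins = int(np.floor(session.duration_s / bin_size + _TIME_TOL))
    if n_bins < 2:
        raise PhiSpikeError("fewer than 2 bins: bin_size too large for session")
    states = np.zeros((len(session.trains), n_bins), dtype=np.int8)
    for row, train in enumerate(session.trains):
        rel = train.spike_times - session.t_start
        idx = np.floor(rel / bin_size).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        states[row, idx] = 1
    return BinnedMatrix(states=states, bin_size=bin_size,
                        neuron_ids=session.neuron_ids, t_start=session.t_start)


def split_periods(binned: BinnedMatrix, n_periods: int) -> list[BinnedMatrix]:
    """Split columns into contiguous near-equal periods (remainder to the front)."""
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if n_periods > binned.n_bins:
        raise PhiSpikeError(
            f"cannot split {binned.n_bins} bins into {n_periods} periods")
    base, rem = divmod(binned.n_bins, n_periods)
    lengths = [base + (1 if i < rem else 0) for i in range(n_periods)]
    out: list[BinnedMatrix] = []
    start = 0
    for length in lengths:
        out.append(BinnedMatrix(
            states=binned.states[:, start:start + length],
            bin_size=binned.bin_size,
            neuron_ids=binned.neuron_ids,
            t_start=binned.t_start + start * binned.bin_size,
        ))
        start += length
    return out
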