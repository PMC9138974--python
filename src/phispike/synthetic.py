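"""Seeded spike-train generators with controllable coupling structure.

The dynamics are a binary linear-threshold network: neuron i fires in
bin t with probability

    clip(base_rate + coupling * mean(parent states at t - delay_bins))

where parents are all other members of the neuron's community block,
plus (with a separate coefficient) members of other blocks.  Spike times
sit at bin centers so re-binarizing at the generating bin size
round-trips the binary matrix exactly.  With coupling 0 the draw path is
identical to the independent generator.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .spike_data import SessionData, SpikeTrain


@dataclass(frozen=True)
class GeneratorSpec:
    n_neurons: int = 20
    duration_s: float = 300.0
    bin_size: float = 0.03
    base_rate: float = 0.1          # expected on-probability per bin
    coupling: float = 0.0
    delay_bins: int = 1
    communities: tuple[int, ...] = ()   # block sizes; empty = one block
    between_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must be a probability")
        if self.coupling < 0 or self.coupling >= 1:
            raise ValueError("coupling must be in [0, 1)")
        if self.delay_bins < 1:
            raise ValueError("delay_bins must be >= 1")
        comms = tuple(int(c) for c in self.communities) or (self.n_neurons,)
        object.__setattr__(self, "communities", comms)
        if sum(comms) != self.n_neurons:
            raise ValueError("community block sizes must sum to n_neurons")

    @property
    def n_bins(self) -> int:
        return int(np.floor(self.duration_s / self.bin_size))

    def block_of(self) -> np.ndarray:
        labels = np.empty(self.n_neurons, dtype=int)
        start = 0
        for b, size in enumerate(self.communities):
            labels[start:start + size] = b
            start += size
        return labels

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _states_to_session(states: np.ndarray, spec: GeneratorSpec,
                       events: Sequence[tuple[float, str]] = ()) -> SessionData:
    trains = []
    width = len(str(spec.n_neurons - 1))
    centers = (np.arange(states.shape[1]) + 0.5) * spec.bin_size
    for i in range(spec.n_neurons):
        times = centers[states[i] > 0]
        trains.append(SpikeTrain(neuron_id=f"n{i:0{width}d}", spike_times=times))
    return SessionData(trains=tuple(trains), events=tuple(events),
                       t_start=0.0, t_end=spec.n_bins * spec.bin_size)


def _simulate_states(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw the binary state matrix; uniform draws are made up-front so the
    coupling-0 path matches the independent generator bit for bit."""
    n, t = spec.n_neurons, spec.n_bins
    u = rng.random((n, t))
    if spec.coupling == 0.0 and spec.between_coupling == 0.0:
        return (u < spec.base_rate).astype(np.int8)
    block = spec.block_of()
    same = block[:, None] == block[None, :]
    within = same.astype(float)
    np.fill_diagonal(within, 0.0)
    between = (~same).astype(float)
    w_norm = within.sum(axis=1)
    b_norm = between.sum(axis=1)
    w_norm[w_norm == 0] = 1.0
    b_norm[b_norm == 0] = 1.0
    states = np.zeros((n, t), dtype=np.int8)
    d = spec.delay_bins
    states[:, :d] = (u[:, :d] < spec.base_rate).astype(np.int8)
    n_clipped = 0
    for j in range(d, t):
        past = states[:, j - d].astype(float)
        drive = (spec.coupling * (within @ past) / w_norm
                 + spec.between_coupling * (between @ past) / b_norm)
        p = spec.base_rate + drive
        n_clipped += int(np.count_nonzero((p < 0) | (p > 1)))
        p = np.clip(p, 0.0, 1.0)
        states[:, j] = (u[:, j] < p).astype(np.int8)
    if n_clipped > 0.01 * n * (t - d):
        _warnings.warn(
            f"probability clipped in {n_clipped} of {n * (t - d)} bin draws",
            RuntimeWarning, stacklevel=3)
    return states


def gen_independent(spec: GeneratorSpec) -> SessionData:
    """Independent Bernoulli(base_rate) bin processes (requires coupling 0)."""
    if spec.coupling != 0.0 or spec.between_coupling != 0.0:
        raise ValueError("gen_independent requires zero coupling")
    rng = np.random.default_rng(spec.seed)
    return _states_to_session(_simulate_states(spec, rng), spec)


def gen_coupled(spec: GeneratorSpec) -> SessionData:
    """Binary linear-threshold network with planted communities and delay."""
    rng = np.random.default_rng(spec.seed)
    return _states_to_session(_simulate_states(spec, rng), spec)


def gen_session_with_rewards(spec: GeneratorSpec, phi_reward_link: float = 0.0,
                             n_periods: int = 8,
                             base_reward_rate: float = 1.0 / 30.0) -> SessionData:
    """Concatenate period blocks with rising coupling and matched reward rates.

    Period p (0-based) runs at coupling ``c_p = spec.coupling * (p+1)/n``;
    rewards are a Poisson process at rate
    ``base_reward_rate * (1 + phi_reward_link * c_p / max(c))`` so that a
    positive link makes reward rate co-vary monotonically with coupling.
    """
    if phi_reward_link < 0:
        raise ValueError("phi_reward_link must be >= 0")
    rng = np.random.default_rng(spec.seed)
    bins_per_period = spec.n_bins // n_periods
    if bins_per_period < spec.delay_bins + spec.n_neurons + 2:
        raise ValueError("periods too short for the system size")
    couplings = [spec.coupling * (p + 1) / n_periods for p in range(n_periods)]
    c_max = max(max(couplings), 1e-12)
    blocks = []
    events: list[tuple[float, str]] = []
    for p, c_p in enumerate(couplings):
        period_spec = GeneratorSpec(
            n_neurons=spec.n_neurons,
            duration_s=bins_per_period * spec.bin_size,
            bin_size=spec.bin_size, base_rate=spec.base_rate, coupling=c_p,
            delay_bins=spec.delay_bins, communities=spec.communities,
            between_coupling=spec.between_coupling, seed=spec.seed)
        blocks.append(_simulate_states(period_spec, rng))
        duration = bins_per_period * spec.bin_size
        rate = base_reward_rate * (1.0 + phi_reward_link * c_p / c_max)
        n_rewards = rng.poisson(rate * duration)
        t0 = p * duration
        for t_rel in np.sort(rng.random(n_rewards)) * duration:
            events.append((t0 + float(t_rel), "reward"))
    states = np.concatenate(blocks, axis=1)
    full_spec = GeneratorSpec(
        n_neurons=spec.n_neurons,
        duration_s=states.shape[1] * spec.bin_size,
        bin_size=spec.bin_size, base_rate=spec.base_rate, coupling=spec.coupling,
        delay_bins=spec.delay_bins, communities=spec.communities,
        between_coupling=spec.between_coupling, seed=spec.seed)
    return _states_to_session(states, full_spec, events)
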