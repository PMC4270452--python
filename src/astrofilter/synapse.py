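"""Stimulation protocols and Tsodyks-Markram glutamate release.

Electrical stimulation of the culture is represented as a train of action
potentials s(t) delivered to an *equivalent synapse* that lumps together all
synapses enwrapped by one stimulated astrocyte.  The synapse follows the
Tsodyks-Markram short-term plasticity model: a facilitation variable u
(decaying to 0 at rate omega_f, incremented by u0*(1-u) at each spike) and a
depression variable x (recovering to 1 at rate omega_d, decremented by the
released fraction r = u+ * x- at each spike).  Each spike adds
``g_release * r`` uM of glutamate to the extracellular pool G, which is
cleared exponentially at rate omega_c.

Because u, x and G obey linear ODEs between spikes, the whole system is
solved exactly event-by-event in closed form; no time step enters the
release amounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import TMParams

__all__ = [
    "SpikeTrain",
    "ProtocolSegment",
    "StimulationProtocol",
    "make_fixed_duration_protocol",
    "make_fixed_count_protocol",
    "GlutamateForcing",
    "tm_release",
    "tm_periodic_steady_state",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (s) within [0, duration]."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must be strictly increasing within [0, duration]")


@dataclass(frozen=True)
class ProtocolSegment:
    frequency: float      # Hz
    n_pulses: int
    t_start: float        # s, absolute onset within the protocol
    duration: float       # s

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def pulse_times(self) -> np.ndarray:
        """Regular pulses at 1/f intervals starting at segment onset."""
        return self.t_start + np.arange(self.n_pulses) / self.frequency


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered stimulation segments separated by silent gaps."""

    segments: tuple[ProtocolSegment, ...]
    inter_segment_gap: float
    order_seed: int | None = None

    def to_json(self) -> str:
        import json
        return json.dumps({
            "inter_segment_gap": self.inter_segment_gap,
            "order_seed": self.order_seed,
            "segments": [{"frequency": s.frequency, "n_pulses": s.n_pulses,
                          "t_start": s.t_start, "duration": s.duration}
                         for s in self.segments],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulationProtocol":
        import json
        d = json.loads(text)
        segs = tuple(ProtocolSegment(**s) for s in d["segments"])
        return cls(segs, d["inter_segment_gap"], d.get("order_seed"))

    @property
    def duration(self) -> float:
        return self.segments[-1].t_end if self.segments else 0.0

    def spike_train(self) -> SpikeTrain:
        if not self.segments:
            return SpikeTrain(np.empty(0), 0.0)
        times = np.concatenate([s.pulse_times() for s in self.segments])
        return SpikeTrain(times, self.duration)

    def stim_intervals(self) -> list[tuple[float, float]]:
        return [(s.t_start, s.t_end) for s in self.segments]


def _assemble(entries: Sequence[tuple[float, int, float]], gap: float,
              order_seed: int | None) -> StimulationProtocol:
    segs = []
    t = 0.0
    for f, n, dur in entries:
        segs.append(ProtocolSegment(frequency=f, n_pulses=n, t_start=t, duration=dur))
        t += dur + gap
    return StimulationProtocol(tuple(segs), gap, order_seed)


def make_fixed_duration_protocol(
    frequencies: Sequence[float], train_duration: float = 30.0, gap: float = 30.0
) -> StimulationProtocol:
    """Pulse trains of fixed duration: ``floor(f * T)`` pulses per segment."""
    if any(f <= 0 for f in frequencies):
        raise ValueError("frequencies must be > 0")
    entries = [(f, int(math.floor(f * train_duration)), train_duration) for f in frequencies]
    return _assemble(entries, gap, None)


def make_fixed_count_protocol(
    frequencies: Sequence[float],
    pulse_count: int = 60,
    gap: float = 30.0,
    order_seed: int | None = None,
) -> StimulationProtocol:
    """Fixed number of pulses per segment (duration inversely related to f);
    segment order randomly permuted when ``order_seed`` is given."""
    if pulse_count < 1:
        raise ValueError("pulse_count must be >= 1")
    if any(f <= 0 for f in frequencies):
        raise ValueError("frequencies must be > 0")
    freqs = list(frequencies)
    if order_seed is not None:
        rng = np.random.default_rng(order_seed)
        freqs = [freqs[i] for i in rng.permutation(len(freqs))]
    entries = [(f, pulse_count, pulse_count / f) for f in freqs]
    return _assemble(entries, gap, order_seed)


@dataclass
class GlutamateForcing:
    """Exact piecewise-exponential glutamate trace G(t) for one synapse.

    ``spike_times`` and ``g_after`` record the state right after each spike;
    between spikes G decays as ``g_after[k] * exp(-omega_c (t - t_k))``.
    Evaluation is vectorised and exact (no integration error).
    """

    spike_times: np.ndarray
    g_after: np.ndarray
    u_after: np.ndarray
    x_after: np.ndarray
    released: np.ndarray   # fraction r = u+ * x- at each spike
    omega_c: float

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.spike_times.size == 0:
            out = np.zeros_like(t)
            return float(out) if out.ndim == 0 else out
        idx = np.searchsorted(self.spike_times, t, side="right") - 1
        valid = idx >= 0
        idx_c = np.clip(idx, 0, None)
        elapsed = np.where(valid, t - self.spike_times[idx_c], 0.0)
        out = np.where(valid, self.g_after[idx_c] * np.exp(-self.omega_c * elapsed), 0.0)
        return float(out) if out.ndim == 0 else out


def tm_events(train: SpikeTrain, params: TMParams) -> GlutamateForcing:
    """Run the exact event-based TM recursion over a spike train.

    At each spike (u decayed to ``u-``, x recovered to ``x-``):
    facilitation first, ``u+ = u- + u0 (1 - u-)``; then release consumes
    resources, ``r = u+ x-``, ``x+ = x- - r``; glutamate jumps by
    ``g_release * r`` on top of its exponential decay.
    """
    t = train.times
    n = t.size
    u_after = np.empty(n)
    x_after = np.empty(n)
    g_after = np.empty(n)
    released = np.empty(n)
    u, x, g = 0.0, 1.0, 0.0
    t_prev = None
    for k in range(n):
        if t_prev is not None:
            dt = t[k] - t_prev
            u *= math.exp(-params.omega_f * dt)
            x = 1.0 - (1.0 - x) * math.exp(-params.omega_d * dt)
            g *= math.exp(-params.omega_c * dt)
        u = u + params.u0 * (1.0 - u)
        r = u * x
        x = x - r
        g = g + params.g_release * r
        u_after[k], x_after[k], g_after[k], released[k] = u, x, g, r
        t_prev = t[k]
    return GlutamateForcing(t.copy(), g_after, u_after, x_after, released, params.omega_c)


def tm_release(
    train: SpikeTrain, params: TMParams, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the glutamate trace G(t) on a uniform grid of step ``dt``.

    Returns ``(time, G)``; the trace itself is computed exactly from the
    event recursion, sampling only discretises the output.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    forcing = tm_events(train, params)
    time = np.arange(0.0, train.duration + 0.5 * dt, dt)
    return time, np.asarray(forcing(time))


def tm_periodic_steady_state(frequency: float, params: TMParams) -> dict[str, float]:
    """Closed-form periodic steady state of the TM recursion at a fixed rate.

    For inter-spike interval T = 1/f, the post-spike facilitation fixed point
    solves ``u+ = e u+ + u0 (1 - e u+)`` with ``e = exp(-omega_f T)``, and the
    pre-spike resource fixed point solves the linear recursion
    ``x-' = 1 - (1 - (1 - u+) x-) exp(-omega_d T)``.  Also returns the mean
    glutamate concentration ``f * g_release * r / omega_c``.
    """
    T = 1.0 / frequency
    ef = math.exp(-params.omega_f * T)
    ed = math.exp(-params.omega_d * T)
    u_plus = (params.u0 * (1.0 - ef) + params.u0 * ef) / (1.0 - ef * (1.0 - params.u0))
    # pre-spike x fixed point: x = 1 - (1 - (1-u+) x) ed  =>  x (1 - ed (1-u+)) = 1 - ed
    x_minus = (1.0 - ed) / (1.0 - ed * (1.0 - u_plus))
    r = u_plus * x_minus
    g_mean = frequency * params.g_release * r / params.omega_c
    return {"u_plus": u_plus, "x_minus": x_minus, "released": r, "g_mean": g_mean}
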