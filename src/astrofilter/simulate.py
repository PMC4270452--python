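"""Network ODE integration under a stimulation protocol.

The per-cell (C, h, I) equations are integrated with a stiff-capable adaptive
solver (LSODA).  Glutamate release is not part of the ODE state: the
Tsodyks-Markram synapse is solved exactly event-by-event (see
:mod:`astrofilter.synapse`) and enters the right-hand side as an analytic
piecewise-exponential forcing, so release amounts carry no time-step error.
Integration is chunked at protocol segment boundaries and the solver step is
bounded below the inter-spike interval within each pulse train.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ._kernel import HAVE_NUMBA, pack_params, rhs_kernel
from .gchi import AstrocyteState, flux_terms, rhs, pack_state, unpack_state
from .network import AstrocyteNetwork
from .params import GChIParams, GJCParams, TMParams
from .synapse import GlutamateForcing, SpikeTrain, StimulationProtocol, tm_events

__all__ = ["TraceSet", "find_rest_state", "simulate", "flux_decomposition",
           "star_network"]


class RestStateError(RuntimeError):
    """The unstimulated cell does not settle to a fixed point (limit cycle
    at rest: parameter regime error)."""


def star_network(k: int, spacing_um: float = 50.0) -> AstrocyteNetwork:
    """One stimulated hub astrocyte coupled to ``k`` unstimulated leaves."""
    if k < 0:
        raise ValueError("k must be >= 0")
    angles = 2 * np.pi * np.arange(max(k, 1)) / max(k, 1)
    pos = np.vstack([[0.0, 0.0],
                     spacing_um * np.column_stack([np.cos(angles), np.sin(angles)])[:k]])
    edges = np.array([[0, i + 1] for i in range(k)], dtype=int).reshape(-1, 2)
    stim = np.zeros(k + 1, dtype=bool)
    stim[0] = True
    return AstrocyteNetwork(tuple(range(k + 1)), pos, edges, stim)


def find_rest_state(
    params: GChIParams,
    tol: float = 1e-9,
    t_max: float = 5000.0,
    y0: tuple[float, float, float] = (0.05, 0.9, 0.05),
) -> AstrocyteState:
    """Resting fixed point of an isolated, unstimulated astrocyte.

    Integrates from ``y0`` with G = 0 until the right-hand side drops below
    ``tol`` (uM/s), then polishes with a root solve.  Raises
    :class:`RestStateError` if no fixed point is approached within ``t_max``
    (the parameter regime oscillates at rest).
    """
    empty_edges = np.empty((0, 2), dtype=int)
    g0 = np.zeros(1)

    def f(t, y):
        return rhs(y, g0, empty_edges, params, None)

    y = np.asarray(y0, dtype=float)
    t = 0.0
    chunk = 200.0
    while t < t_max:
        sol = solve_ivp(f, (t, t + chunk), y, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RestStateError(f"integration failed at t={sol.t[-1]}: {sol.message}")
        y = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(f(t, y))) < max(tol, 1e-7):
            break
    else:
        raise RestStateError("no convergence to rest within time bound; "
                             "parameter regime may oscillate at rest")
    polish = root(lambda z: f(0.0, z), y, tol=1e-13)
    if polish.success and np.max(np.abs(f(0.0, polish.x))) < tol:
        y = polish.x
    if np.max(np.abs(f(0.0, y))) >= tol:
        raise RestStateError("rest state residual above tolerance")
    return AstrocyteState(C=float(y[0]), h=float(y[1]), I=float(y[2]))


@dataclass(frozen=True)
class TraceSet:
    """Sampled simulation output on a uniform grid.

    ``C``, ``h``, ``I`` are (n_cells, n_times); ``G`` is the shared
    glutamate trace of the equivalent synapse driving every stimulated cell
    (identical across stimulated cells by construction).  ``segments`` holds
    the absolute (t_start, t_end) of each stimulation segment.
    """

    time: np.ndarray
    C: np.ndarray
    h: np.ndarray
    I: np.ndarray
    G: np.ndarray
    segments: tuple[tuple[float, float], ...]
    network: AstrocyteNetwork
    rest: AstrocyteState

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def normalized(self) -> np.ndarray:
        """(C - C_rest) / C_rest, the model analogue of dF/F0."""
        return (self.C - self.rest.C) / self.rest.C

    def to_csv(self, path: str | Path) -> None:
        ids = self.network.astrocyte_ids
        data = {"time_s": self.time}
        for k, cid in enumerate(ids):
            data[f"C_{cid}"] = self.C[k]
        for k, cid in enumerate(ids):
            data[f"I_{cid}"] = self.I[k]
        data["G_synapse"] = self.G
        pd.DataFrame(data).to_csv(path, index=False)

    def sidecar(self) -> dict:
        return {
            "dt_out": self.dt,
            "segments": [list(s) for s in self.segments],
            "rest_state": {"C": self.rest.C, "h": self.rest.h, "I": self.rest.I},
            "n_astrocytes": self.network.n_astrocytes,
            "stimulated_ids": list(map(int, self.network.stimulated_ids)),
        }


def simulate(
    net: AstrocyteNetwork,
    protocol: StimulationProtocol,
    gchi: GChIParams,
    gjc: GJCParams,
    tm: TMParams,
    dt_out: float = 0.1,
    pre_time: float = 30.0,
    post_time: float = 0.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    rest: AstrocyteState | None = None,
    use_kernel: bool = True,
) -> TraceSet:
    """Integrate the coupled network under a stimulation protocol.

    All cells start at the resting fixed point; stimulated cells share one
    equivalent synapse driven by the protocol's pulse train, delayed by
    ``pre_time`` (a silent span used as the spontaneous-activity window).
    Deterministic given its inputs.
    """
    if rest is None:
        rest = find_rest_state(gchi)
    n = net.n_astrocytes
    if n == 0:
        raise ValueError("empty network")

    train = protocol.spike_train()
    spike_times = train.times + pre_time
    total = pre_time + protocol.duration + post_time
    forcing = (tm_events(SpikeTrain(spike_times, total), tm)
               if spike_times.size else None)
    stim_mask = net.stimulated.astype(float)

    def g_inputs(t: float) -> np.ndarray:
        if forcing is None:
            return np.zeros(n)
        return stim_mask * forcing(t)

    if use_kernel and HAVE_NUMBA:
        stim_b = net.stimulated.astype(np.bool_)
        sp_t = forcing.spike_times if forcing is not None else np.empty(0)
        sp_g = forcing.g_after if forcing is not None else np.empty(0)
        om_c = forcing.omega_c if forcing is not None else 1.0
        e_i = np.ascontiguousarray(net.edges[:, 0], dtype=np.int64)
        e_j = np.ascontiguousarray(net.edges[:, 1], dtype=np.int64)
        pvec = pack_params(gchi, gjc)

        def f(t, y):
            return rhs_kernel(t, y, stim_b, sp_t, sp_g, om_c, e_i, e_j, pvec)
    else:
        def f(t, y):
            return rhs(y, g_inputs(t), net.edges, gchi, gjc)

    time = np.round(np.arange(0.0, total + 0.5 * dt_out, dt_out), 9)
    y0 = np.tile(rest.as_array().reshape(3, 1), (1, n)).reshape(3, n)
    y = pack_state(y0[0], y0[1], y0[2])

    # chunk boundaries: segment edges (shifted by pre_time), plus start/end
    cuts = {0.0, total}
    seg_abs = []
    for s in protocol.segments:
        a, b = s.t_start + pre_time, s.t_end + pre_time
        seg_abs.append((a, b))
        cuts.update((a, min(b, total)))
    cuts = sorted(c for c in cuts if 0.0 <= c <= total)

    out = np.empty((3 * n, time.size))
    out[:, 0] = y
    filled = np.zeros(time.size, dtype=bool)
    filled[0] = True
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a <= 0:
            continue
        # step bound: resolve every inter-spike interval inside pulse trains
        f_here = [s.frequency for s, (sa, sb) in zip(protocol.segments, seg_abs)
                  if sa < b and sb > a]
        max_step = min([0.45 / fr for fr in f_here] + [1.0])
        mask = (time > a + 1e-12) & (time <= b + 1e-12)
        t_eval = np.unique(np.concatenate([time[mask], [b]]))
        sol = solve_ivp(f, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                        max_step=max_step, t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"solver failure in [{a}, {b}] s: {sol.message}; "
                               f"state at failure: {sol.y[:, -1] if sol.y.size else y}")
        y = sol.y[:, -1]
        if mask.any():
            # map evaluated points back onto the global grid
            idx = np.searchsorted(sol.t, time[mask])
            out[:, mask] = sol.y[:, np.clip(idx, 0, sol.t.size - 1)]
            filled[mask] = True
    if not filled.all():
        raise RuntimeError("output grid not fully covered by integration chunks")

    C, h, I = (out[:n], out[n:2 * n], out[2 * n:])
    if C.min() < -1e-6 or I.min() < -1e-6 or h.min() < -1e-6 or h.max() > 1 + 1e-6:
        raise RuntimeError("state positivity/bounds violated along trajectory")
    G = np.asarray(forcing(time)) if forcing is not None else np.zeros_like(time)
    return TraceSet(time=time, C=np.clip(C, 0.0, None), h=np.clip(h, 0.0, 1.0),
                    I=np.clip(I, 0.0, None), G=G,
                    segments=tuple(seg_abs), network=net, rest=rest)


def flux_decomposition(traces: TraceSet, gchi: GChIParams, cell: int = 0) -> pd.DataFrame:
    """Evaluate the seven model fluxes along the trajectory of one cell.

    Reproduces the signalling-pathway decomposition of a response: PLCbeta
    input, the PLCdelta surge at CICR onset, Ca-dependent 3K degradation
    during the rise, and the CICR/leak/SERCA calcium fluxes.
    """
    g = traces.G if traces.network.stimulated[cell] else np.zeros_like(traces.G)
    fl = flux_terms({"C": traces.C[cell], "h": traces.h[cell], "I": traces.I[cell]},
                    g, gchi)
    df = pd.DataFrame(fl)
    df.insert(0, "time_s", traces.time)
    return df
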