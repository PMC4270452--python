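"""Frequency-sweep experiments on model astrocyte networks.

These functions assemble the building blocks (protocols, network simulation,
responsiveness, wavelet spectra) into the standard in-silico experiments:
dense responsiveness sweeps with exact-onset extraction, oscillation
frequency vs stimulation frequency, and response-initiation / gap-junction
transmission delays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import AstrocyteNetwork
from .params import GChIParams, GJCParams, TMParams
from .response import (OnsetEstimate, ResponseCurve, StimWindows,
                       exact_onset_frequency, response_delay, responsiveness)
from .simulate import AstrocyteState, TraceSet, find_rest_state, simulate, star_network
from .spectral import CUTOFF_HZ, spectral_profile
from .synapse import make_fixed_duration_protocol

__all__ = [
    "single_frequency_run",
    "responsiveness_sweep",
    "exact_onset_for_degree",
    "oscillation_frequency_sweep",
    "count_transients",
    "stimulated_response_delay",
    "transmission_delay",
]

# dF/F0 threshold above which an excursion counts as a Ca2+ transient; model
# spikes reach dF/F0 ~ 30, sub-threshold drift stays < 1.
TRANSIENT_DFF_THRESHOLD = 5.0


def single_frequency_run(
    net: AstrocyteNetwork,
    frequency_hz: float,
    gchi: GChIParams,
    gjc: GJCParams,
    tm: TMParams,
    train_s: float = 30.0,
    pre_s: float = 30.0,
    post_s: float = 0.0,
    rest: AstrocyteState | None = None,
) -> TraceSet:
    """Simulate one pulse train at a single frequency, preceded by a silent
    spontaneous window."""
    protocol = make_fixed_duration_protocol([frequency_hz], train_duration=train_s, gap=0.0)
    return simulate(net, protocol, gchi, gjc, tm, pre_time=pre_s, post_time=post_s, rest=rest)


def responsiveness_sweep(
    net: AstrocyteNetwork,
    frequencies: np.ndarray,
    gchi: GChIParams,
    gjc: GJCParams,
    tm: TMParams,
    cell: int = 0,
    train_s: float = 30.0,
    pre_s: float = 30.0,
    rest: AstrocyteState | None = None,
) -> ResponseCurve:
    """Single-cell responsiveness of ``cell`` vs stimulation frequency.

    Each frequency is an independent run from rest: a ``pre_s`` spontaneous
    window followed by a ``train_s`` pulse train; responsiveness is the
    difference of per-unit-time normalized Ca2+ between the two windows.
    """
    if rest is None:
        rest = find_rest_state(gchi)
    rs = []
    for f in np.asarray(frequencies, dtype=float):
        traces = single_frequency_run(net, f, gchi, gjc, tm, train_s, pre_s, rest=rest)
        windows = StimWindows(stim=((pre_s, pre_s + train_s),), spont=(0.0, pre_s - 1e-9))
        rs.append(responsiveness(traces.normalized()[cell], traces.time, windows))
    return ResponseCurve(np.asarray(frequencies, dtype=float), np.array(rs))


def exact_onset_for_degree(
    k: int,
    frequencies: np.ndarray,
    gchi: GChIParams,
    gjc: GJCParams,
    tm: TMParams,
    rest: AstrocyteState | None = None,
) -> tuple[OnsetEstimate, ResponseCurve]:
    """Exact onset frequency of a stimulated astrocyte coupled to ``k``
    unstimulated neighbours (star network), from the derivative peak of its
    densely sampled responsiveness curve."""
    net = star_network(k)
    curve = responsiveness_sweep(net, frequencies, gchi, gjc, tm, rest=rest)
    return exact_onset_frequency(curve), curve


def count_transients(dff: np.ndarray, threshold: float = TRANSIENT_DFF_THRESHOLD) -> int:
    """Number of upward threshold crossings of a normalized Ca2+ trace."""
    above = dff > threshold
    return int(np.count_nonzero(above[1:] & ~above[:-1]))


def oscillation_frequency_sweep(
    k: int,
    frequencies: np.ndarray,
    gchi: GChIParams,
    gjc: GJCParams,
    tm: TMParams,
    train_s: float = 90.0,
    pre_s: float = 30.0,
    post_s: float = 30.0,
    min_transients: int = 3,
    rest: AstrocyteState | None = None,
) -> pd.DataFrame:
    """Mean and maximal oscillating frequency of the stimulated hub vs
    stimulation frequency, via the Morlet pipeline.

    A frequency estimate requires repeated events within the analyzed band:
    sweep points where the hub shows fewer than ``min_transients`` Ca2+
    transients, or whose event rate falls below the 0.07 Hz analysis cutoff
    (rhythms slower than the band floor cannot be measured by the wavelet
    pipeline; the argmax would reflect single-transient width instead), are
    reported as NaN.
    """
    if rest is None:
        rest = find_rest_state(gchi)
    net = star_network(k)
    rows = []
    for f in np.asarray(frequencies, dtype=float):
        traces = single_frequency_run(net, f, gchi, gjc, tm, train_s, pre_s, post_s, rest=rest)
        dff = traces.normalized()[0]
        window = (traces.time >= pre_s) & (traces.time <= pre_s + train_s)
        n_ev = count_transients(dff[window])
        if n_ev < min_transients or n_ev / train_s < CUTOFF_HZ:
            rows.append((f, n_ev, np.nan, np.nan))
            continue
        prof = spectral_profile(dff, traces.dt, ((pre_s, pre_s + train_s),),
                                times=traces.time)
        rows.append((f, n_ev,
                     prof.mean_freq_hz if prof.oscillating else np.nan,
                     prof.max_freq_hz if prof.oscillating else np.nan))
    return pd.DataFrame(rows, columns=["stim_freq_hz", "n_transients",
                                       "mean_osc_freq_hz", "max_osc_freq_hz"])


def stimulated_response_delay(
    gchi: GChIParams,
    gjc: GJCParams,
    tm: TMParams,
    frequency_hz: float = 70.0,
    train_s: float = 30.0,
    rest: AstrocyteState | None = None,
) -> float | None:
    """Response-initiation delay (60%-of-maximum criterion) of an isolated
    directly stimulated astrocyte."""
    traces = single_frequency_run(star_network(0), frequency_hz, gchi, gjc, tm,
                                  train_s, 30.0, rest=rest)
    return response_delay(traces.normalized()[0], traces.time, 30.0, 30.0 + train_s,
                          min_amplitude=0.3)


def transmission_delay(
    gchi: GChIParams,
    gjc: GJCParams,
    tm: TMParams,
    frequency_hz: float = 10.0,
    train_s: float = 30.0,
    span_s: float = 60.0,
    rest: AstrocyteState | None = None,
) -> dict[str, float | None]:
    """Delay for a Ca2+ signal to reach a GJC-coupled unstimulated neighbour.

    Two-astrocyte network, one stimulated; both response-initiation times use
    the 60% criterion over ``span_s`` after stimulation start.  Returns the
    hub delay, the neighbour delay and their difference (None where a cell
    never responds).
    """
    traces = single_frequency_run(star_network(1), frequency_hz, gchi, gjc, tm,
                                  train_s, 30.0, post_s=span_s - train_s, rest=rest)
    dff = traces.normalized()
    hub = response_delay(dff[0], traces.time, 30.0, 30.0 + span_s, min_amplitude=0.3)
    leaf = response_delay(dff[1], traces.time, 30.0, 30.0 + span_s, min_amplitude=0.3)
    diff = None if hub is None or leaf is None else leaf - hub
    return {"hub_delay_s": hub, "neighbour_delay_s": leaf, "transmission_delay_s": diff}
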