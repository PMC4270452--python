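"""Responsiveness, onset-frequency fitting and response-delay classification.

The *responsiveness* r of a cell at a given stimulation frequency is the
time-averaged normalized Ca2+ signal inside the stimulation windows minus the
same average over a spontaneous (unstimulated) window; it is dimensionless
and reported in arbitrary units (AU).

Responsiveness-vs-frequency curves are summarised in two ways, mirroring how
sparse experimental sweeps and dense model sweeps are treated:

* a four-parameter logistic fit ``R(f) = A + (B - A) / (1 + exp(-(f - C)/tau))``
  whose 10%-of-maximum point defines the *onset frequency* (with a fallback
  exponential-rise fit when no upper plateau is reached), and
* the *exact onset frequency*: the stimulation frequency at the peak of the
  normalized numerical derivative of a densely sampled curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StimWindows",
    "ResponseCurve",
    "LogisticFit",
    "OnsetEstimate",
    "normalize_trace",
    "responsiveness",
    "fit_logistic",
    "onset_frequency",
    "exact_onset_frequency",
    "response_delay",
    "classify_stimulated",
]

STIMULATED_DELAY_THRESHOLD_S = 1.5   # max delay for a directly stimulated cell
DELAY_FRACTION = 0.60                # response initiation: 60% of segment max
ONSET_FRACTION = 0.10                # onset: 10% of fitted maximum


@dataclass(frozen=True)
class StimWindows:
    """Stimulation intervals and one spontaneous interval, in trace time."""

    stim: tuple[tuple[float, float], ...]
    spont: tuple[float, float]

    def __post_init__(self) -> None:
        ivals = sorted(list(self.stim) + [self.spont])
        for (a0, b0), (a1, b1) in zip(ivals[:-1], ivals[1:]):
            if b0 > a1 + 1e-12:
                raise ValueError("windows overlap")
        if any(b <= a for a, b in ivals):
            raise ValueError("empty window")


def normalize_trace(series: np.ndarray, rest_value: float) -> np.ndarray:
    """Map a Ca2+ trace to the dF/F0-like observable (C - C_rest)/C_rest."""
    if rest_value <= 0:
        raise ValueError("rest value must be > 0")
    return (np.asarray(series, dtype=float) - rest_value) / rest_value


def responsiveness(series: np.ndarray, time: np.ndarray, windows: StimWindows) -> float:
    """Per-unit-time signal in stimulation windows minus spontaneous signal.

    With uniform sampling, the per-unit-time normalization reduces to the
    mean of the in-window samples.
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    stim_mask = np.zeros_like(time, dtype=bool)
    for a, b in windows.stim:
        stim_mask |= (time >= a) & (time <= b)
    a, b = windows.spont
    spont_mask = (time >= a) & (time <= b)
    if not stim_mask.any() or not spont_mask.any():
        raise ValueError("a window contains no samples")
    return float(series[stim_mask].mean() - series[spont_mask].mean())


@dataclass(frozen=True)
class ResponseCurve:
    """Single-cell (or population-mean) responsiveness vs stimulation frequency."""

    frequencies: np.ndarray
    r: np.ndarray
    label: str = "single-cell"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "r", r)
        if f.ndim != 1 or f.shape != r.shape:
            raise ValueError("frequencies and r must be 1D of equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class LogisticFit:
    """Four-parameter logistic fit of a responsiveness curve.

    A: minimum plateau, B: maximum plateau, C: 50% point (Hz), tau: slope
    scale (Hz).  ``mode`` is "sigmoid" for the full fit and "exponential"
    when the curve never plateaus and only the rising limb is fitted;
    ``ok`` is False for degenerate/non-converged fits.
    """

    A: float
    B: float
    C: float
    tau: float
    covariance: np.ndarray | None
    residual_rms: float
    mode: str = "sigmoid"
    ok: bool = True

    def __call__(self, f: np.ndarray | float) -> np.ndarray | float:
        if self.mode == "exponential":
            return self.A + (self.B - self.A) * np.exp((np.asarray(f) - self.C) / self.tau)
        return _logistic4(np.asarray(f), self.A, self.B, self.C, self.tau)


def _logistic4(f, A, B, C, tau):
    return A + (B - A) / (1.0 + np.exp(-(f - C) / tau))


def fit_logistic(curve: ResponseCurve) -> LogisticFit:
    """Least-squares four-parameter logistic fit with B >= A and tau > 0.

    If the fitted midpoint lies beyond the sampled range (no plateau reached),
    the result is re-fitted on the exponential rising limb of the sigmoid and
    flagged via ``mode="exponential"``.
    """
    f, r = curve.frequencies, curve.r
    if f.size < 4:
        raise ValueError("need at least 4 frequency points")
    span = float(r.max() - r.min())
    if span <= 0 or span < 1e-12 * max(1.0, abs(float(r.max()))):
        return LogisticFit(float(r.mean()), float(r.mean()), float(np.median(f)),
                           1.0, None, 0.0, mode="sigmoid", ok=False)
    # B >= A enforced by fitting dB = B - A >= 0
    def model(x, A, dB, C, tau):
        return _logistic4(x, A, A + dB, C, tau)

    p0 = [float(r.min()), span, float(np.interp(r.min() + span / 2, r, f)),
          max(0.25 * (f.max() - f.min()) / 4, 1e-3)]
    # the midpoint is a frequency: keep it non-negative and near the sweep
    bounds = ([-np.inf, 0.0, 0.0, 1e-9],
              [np.inf, np.inf, 3.0 * float(f.max()), np.inf])
    popt = pcov = None
    try:
        popt, pcov = curve_fit(model, f, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        pass
    if popt is not None:
        A, dB, C, tau = popt
        resid = r - model(f, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
    if popt is None or C > f.max():
        # no upper plateau within the sweep: fit the exponential rising limb
        def exp_model(x, A, a, tau):
            return A + a * np.exp(x / tau)
        try:
            t0 = max((f.max() - f.min()) / 3, 1e-3)
            a0 = max((r[-1] - r[0]) / (np.exp(f.max() / t0) - np.exp(f.min() / t0)),
                     1e-9)
            q0 = [float(r[0] - a0 * np.exp(f.min() / t0)), a0, t0]
            qopt, qcov = curve_fit(exp_model, f, r, p0=q0, maxfev=20000,
                                   bounds=([-np.inf, 1e-12, 1e-9],
                                           [np.inf, np.inf, np.inf]))
            Aq, aq, tq = qopt
            # represent as A + (B-A) exp((f-C)/tau) with C at the sweep top
            Ce = f.max()
            Be = Aq + aq * np.exp(Ce / tq)
            rmsq = float(np.sqrt(np.mean((r - exp_model(f, *qopt)) ** 2)))
            return LogisticFit(float(Aq), float(Be), float(Ce), float(tq),
                               qcov, rmsq, mode="exponential", ok=True)
        except RuntimeError:
            pass
    if popt is None:
        return LogisticFit(p0[0], p0[0] + p0[1], p0[2], p0[3], None, float("nan"),
                           mode="sigmoid", ok=False)
    return LogisticFit(float(A), float(A + dB), float(C), float(tau), pcov, rms,
                       mode="sigmoid", ok=True)


@dataclass(frozen=True)
class OnsetEstimate:
    frequency_hz: float
    ci95: tuple[float, float] | None = None
    ok: bool = True
    note: str = ""


def onset_frequency(fit: LogisticFit) -> OnsetEstimate:
    """Frequency at which the fitted responsiveness is 10% of its maximum.

    For the sigmoid mode this inverts the logistic:
    ``f_onset = C - tau * ln((1 - q)/q)`` with q = 0.10, i.e. C - tau ln 9.
    The 95% CI is propagated from the fit covariance of (C, tau).
    """
    if not fit.ok or not (fit.B > fit.A):
        return OnsetEstimate(float("nan"), None, ok=False, note="degenerate fit")
    q = ONSET_FRACTION
    ln9 = float(np.log((1 - q) / q))
    if fit.mode == "exponential":
        # A + a exp(f/tau) = A + q (R(C) - A)  with R(C)=B at the sweep top
        f_on = fit.C + fit.tau * float(np.log(q))
        return OnsetEstimate(float(f_on), None, ok=True, note="exponential-rise fit")
    f_on = fit.C - fit.tau * ln9
    ci = None
    if fit.covariance is not None and fit.covariance.shape == (4, 4):
        # parameter order in covariance: (A, dB, C, tau)
        grad = np.array([0.0, 0.0, 1.0, -ln9])
        var = float(grad @ fit.covariance @ grad)
        if np.isfinite(var) and var >= 0:
            half = 1.96 * np.sqrt(var)
            ci = (f_on - half, f_on + half)
    return OnsetEstimate(float(f_on), ci, ok=True)


def exact_onset_frequency(curve: ResponseCurve) -> OnsetEstimate:
    """Inflection-point onset of a densely sampled responsiveness curve.

    Returns the frequency at the maximum of the normalized numerical
    derivative (dR/df)/max(dR/df); flagged when the derivative is flat
    (no inflection, e.g. a linear curve).
    """
    f, r = curve.frequencies, curve.r
    if f.size < 7:
        raise ValueError("need at least 7 points for the exact onset")
    d = np.gradient(r, f)
    dmax = d.max()
    if dmax <= 0 or (d.max() - d.min()) <= 1e-9 * max(abs(dmax), 1e-30):
        return OnsetEstimate(float("nan"), None, ok=False, note="flat derivative")
    return OnsetEstimate(float(f[int(np.argmax(d))]), None, ok=True)


def response_delay(
    series: np.ndarray,
    time: np.ndarray,
    stim_start: float,
    stim_end: float | None = None,
    min_amplitude: float = 0.05,
) -> float | None:
    """Response-initiation delay: first time after stimulation start at which
    the normalized signal exceeds 60% of its maximum over the analysis span.

    Returns None when the cell never responds (maximum below
    ``min_amplitude`` in dF/F0 units, or no crossing).
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    mask = time >= stim_start
    if stim_end is not None:
        mask &= time <= stim_end
    if not mask.any():
        raise ValueError("empty stimulation window")
    peak = series[mask].max()
    if peak <= min_amplitude:
        return None
    idx = np.nonzero(mask & (series >= DELAY_FRACTION * peak))[0]
    if idx.size == 0:
        return None
    return float(time[idx[0]] - stim_start)


def classify_stimulated(delay: float | None) -> bool:
    """A cell is *stimulated* (directly driven, not GJC-relayed) iff it
    responded with a delay under 1.5 s."""
    return delay is not None and delay < STIMULATED_DELAY_THRESHOLD_S
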