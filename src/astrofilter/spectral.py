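"""Morlet-wavelet time-frequency analysis of Ca2+ traces.

Astrocytic Ca2+ signals are strongly non-stationary, so oscillation content
is quantified on the continuous wavelet transform (Morlet basis) rather than
a Fourier spectrum.  The analysis restricts the time-frequency plane to
in-stimulation time points carrying at least one coefficient above 70% of
the cell's largest coefficient, discards pseudo-frequencies below a 0.07 Hz
cutoff (which removes the 1/30 s = 0.033 Hz protocol line), extracts one
*representative frequency* per surviving time point (the per-time argmax),
and summarises each cell by the mean and the 95th percentile ("maximal
oscillating frequency") of its representative-frequency distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.mixture import GaussianMixture

__all__ = [
    "WaveletPlane",
    "SpectralProfile",
    "cwt_morlet",
    "restrict_plane",
    "representative_frequencies",
    "max_oscillating_frequency",
    "spectral_profile",
    "classify_response_types",
    "TypeClassification",
]

WAVELET = "morl"                 # real-valued Morlet; center frequency 0.8125
THRESHOLD_FRACTION = 0.70        # coefficient restriction threshold
CUTOFF_HZ = 0.07                 # removes the 0.033 Hz stimulation line
DEFAULT_BAND = (0.07, 0.5)       # Hz, covers all astrocyte oscillation bands
DEFAULT_N_SCALES = 64


@dataclass(frozen=True)
class WaveletPlane:
    """Magnitude of the CWT: rows are pseudo-frequencies (ascending), columns
    time points."""

    magnitude: np.ndarray        # (n_freqs, n_times)
    frequencies: np.ndarray      # Hz, ascending
    times: np.ndarray            # s


def cwt_morlet(
    series: np.ndarray,
    dt: float,
    frequency_band: tuple[float, float] = DEFAULT_BAND,
    n_scales: int = DEFAULT_N_SCALES,
    times: np.ndarray | None = None,
) -> WaveletPlane:
    """Morlet CWT on a log-uniform pseudo-frequency grid.

    Pseudo-frequency and scale are related through the wavelet center
    frequency: f = fc / (scale * dt).
    """
    series = np.asarray(series, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    nyquist = 0.5 / dt
    lo, hi = frequency_band
    if not 0 < lo < hi:
        raise ValueError("invalid frequency band")
    if hi > nyquist:
        raise ValueError(f"band top {hi} Hz above Nyquist {nyquist} Hz")
    freqs = np.geomspace(lo, hi, n_scales)
    fc = pywt.central_frequency(WAVELET)
    scales = fc / (freqs * dt)
    coef, _ = pywt.cwt(series, scales, WAVELET, sampling_period=dt)
    if times is None:
        times = np.arange(series.size) * dt
    return WaveletPlane(np.abs(coef), freqs, np.asarray(times, dtype=float))


@dataclass(frozen=True)
class RestrictedPlane:
    magnitude: np.ndarray        # (n_freqs_kept, n_times_kept)
    frequencies: np.ndarray
    times: np.ndarray            # surviving time points

    @property
    def empty(self) -> bool:
        return self.times.size == 0


def restrict_plane(
    plane: WaveletPlane,
    stim_windows: tuple[tuple[float, float], ...],
    threshold_fraction: float = THRESHOLD_FRACTION,
    cutoff_hz: float = CUTOFF_HZ,
) -> RestrictedPlane:
    """Keep frequencies above the cutoff and in-window time points whose
    column carries a coefficient >= threshold_fraction of the cell's global
    maximum.  An empty restriction means the cell is deemed non-oscillating.
    """
    frow = plane.frequencies >= cutoff_hz
    mag = plane.magnitude[frow]
    freqs = plane.frequencies[frow]
    inwin = np.zeros(plane.times.size, dtype=bool)
    for a, b in stim_windows:
        inwin |= (plane.times >= a) & (plane.times <= b)
    gmax = mag.max() if mag.size else 0.0
    if gmax <= 0:
        keep = np.zeros_like(inwin)
    else:
        keep = inwin & (mag.max(axis=0) >= threshold_fraction * gmax)
    return RestrictedPlane(mag[:, keep], freqs, plane.times[keep])


def representative_frequencies(restricted: RestrictedPlane) -> np.ndarray:
    """Per surviving time point, the frequency of the largest coefficient.

    Exact ties are broken toward the lower frequency (rows are ascending and
    argmax returns the first maximum).
    """
    if restricted.empty:
        raise ValueError("empty restricted plane")
    return restricted.frequencies[np.argmax(restricted.magnitude, axis=0)]


def max_oscillating_frequency(rep_freqs: np.ndarray) -> float:
    """95th percentile of the representative-frequency distribution (linear
    interpolation between order statistics); robust to argmax artifacts that
    would corrupt a plain maximum."""
    rep_freqs = np.asarray(rep_freqs, dtype=float)
    if rep_freqs.size == 0:
        raise ValueError("empty distribution")
    return float(np.percentile(rep_freqs, 95))


@dataclass(frozen=True)
class SpectralProfile:
    """Per-cell summary of the wavelet analysis."""

    rep_freqs: np.ndarray            # Hz, one per surviving time point
    mean_freq_hz: float | None       # mean oscillating frequency
    max_freq_hz: float | None        # 95th-percentile maximal frequency
    oscillating: bool
    response_type: str = "unlabeled"   # "I" | "II" | "unlabeled"


def spectral_profile(
    series: np.ndarray,
    dt: float,
    stim_windows: tuple[tuple[float, float], ...],
    frequency_band: tuple[float, float] = DEFAULT_BAND,
    n_scales: int = DEFAULT_N_SCALES,
    times: np.ndarray | None = None,
) -> SpectralProfile:
    """Full per-cell pipeline: CWT, restriction, representative frequencies,
    mean and maximal oscillating frequency."""
    plane = cwt_morlet(series, dt, frequency_band, n_scales, times=times)
    restricted = restrict_plane(plane, stim_windows)
    if restricted.empty:
        return SpectralProfile(np.empty(0), None, None, oscillating=False)
    rep = representative_frequencies(restricted)
    return SpectralProfile(rep, float(rep.mean()), max_oscillating_frequency(rep),
                           oscillating=True)


@dataclass(frozen=True)
class TypeClassification:
    labels: tuple[str, ...]          # per cell: "I" | "II" | "unlabeled"
    means_hz: tuple[float, ...]      # component means, ascending
    weights: tuple[float, ...]
    bimodal: bool


def classify_response_types(
    max_freqs: np.ndarray,
    random_state: int = 0,
    min_weight: float = 0.05,
) -> TypeClassification:
    """Two-component Gaussian mixture on maximal oscillating frequencies.

    Cells in the low-frequency component (~0.1 Hz) are Type I (coupling-
    dominated, stimulation-independent oscillations), cells in the high
    component (~0.2 Hz) Type II.  Falls back to a single component (all
    cells unlabeled) when the histogram is not credibly bimodal.
    """
    x = np.asarray(max_freqs, dtype=float).reshape(-1, 1)
    n = x.shape[0]
    if n < 4 or np.ptp(x) < 1e-9:
        return TypeClassification(("unlabeled",) * n, (float(np.mean(x)),), (1.0,), False)
    gm2 = GaussianMixture(2, random_state=random_state, n_init=5).fit(x)
    gm1 = GaussianMixture(1, random_state=random_state).fit(x)
    order = np.argsort(gm2.means_.ravel())
    means = gm2.means_.ravel()[order]
    sds = np.sqrt(gm2.covariances_.ravel()[order])
    weights = gm2.weights_.ravel()[order]
    separated = (means[1] - means[0]) > max(sds.mean(), 1e-6)
    bimodal = (gm2.bic(x) < gm1.bic(x)) and weights.min() >= min_weight and separated
    if not bimodal:
        return TypeClassification(("unlabeled",) * n,
                                  tuple(float(m) for m in means),
                                  tuple(float(w) for w in weights), False)
    post = gm2.predict_proba(x)[:, order]
    labels = tuple("I" if p0 >= p1 else "II" for p0, p1 in post)
    return TypeClassification(labels, tuple(float(m) for m in means),
                              tuple(float(w) for w in weights), True)
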