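"""Waveform statistics for current-dipole time series.

Implements the analysis layer used to characterize simulated (or external)
current-source signals:

* Morlet-wavelet spectrogram over 1-150 Hz (``P_M``, signal units squared);
* stationary Welch periodogram of the full analysis window, Hann tapered
  (``P_W``);
* prominence-filtered local extrema and the per-cycle slope ratio
  ``phi_i = |m_rise_i| / |m_fall_i|`` with its mean ``Phi``, standard error
  and one-sided t-test against 1;
* spike histograms (1 ms bins) and peristimulus time histograms (5 ms bins);
* detection of transient high-gamma (100-150 Hz) epochs as local maxima of
  band-limited Morlet power, each reported with a 50 ms window.

All operations accept plain (time, value) arrays, so they apply equally to
simulator output and to externally supplied two-column series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as sstats
from scipy.ndimage import gaussian_filter1d, median_filter


# ---------------------------------------------------------------------------
# spectral estimates
# ---------------------------------------------------------------------------

@dataclass
class Spectrogram:
    """Time-frequency power (signal units squared) on a (freq, time) grid."""

    t: np.ndarray          # ms
    f: np.ndarray          # Hz
    power: np.ndarray      # shape (n_freqs, n_times), >= 0

    def band(self, fmin: float, fmax: float) -> "Spectrogram":
        m = (self.f >= fmin) & (self.f <= fmax)
        return Spectrogram(self.t, self.f[m], self.power[m])

    @property
    def peak(self) -> tuple[float, float, float]:
        """(time_ms, freq_Hz, power) of the global maximum."""
        i, j = np.unravel_index(np.argmax(self.power), self.power.shape)
        return float(self.t[j]), float(self.f[i]), float(self.power[i, j])


@dataclass
class Periodogram:
    """Stationary Welch periodogram (Hann tapered), power in signal units^2."""

    f: np.ndarray
    power: np.ndarray
    taper: str = "hann"

    def peak(self, fmin: float = 0.0, fmax: float = np.inf) -> tuple[float, float]:
        """(freq_Hz, power) of the maximum within [fmin, fmax]."""
        m = (self.f >= fmin) & (self.f <= fmax)
        if not np.any(m):
            raise ValueError("empty frequency range")
        i = np.argmax(self.power[m])
        return float(self.f[m][i]), float(self.power[m][i])


def _as_series(t, x):
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if t.ndim != 1 or t.shape != x.shape or t.size < 2:
        raise ValueError("need matching 1-d time and value arrays (>= 2 samples)")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("series must be uniformly sampled")
    return t, x, float(dt[0])


def morlet_spectrogram(t, x, fmin: float = 1.0, fmax: float = 150.0,
                       df: float = 1.0, n_cycles: float = 11.0,
                       detrend: bool = True) -> Spectrogram:
    """Morlet-wavelet spectrogram of a uniformly sampled series.

    Complex Morlet wavelets with ``n_cycles`` cycles (Gaussian s.d.
    ``n_cycles / (2 pi f)`` in time) are convolved with the zero-padded,
    mean-removed signal; power is the squared magnitude scaled so a unit
    sinusoid at a resolved frequency has peak power ~1/4 per side.  The
    default width of 11 cycles suits stationary 500 ms analysis windows:
    at constant Q the spectral bandwidth is f/11, narrow enough that the
    peak frequency of a noisy gamma rhythm is not biased downward by the
    broadband background (wider bands integrate more 1/f power at low f).  For
    window lengths shorter than the nominal wavelet support the lowest
    frequencies are edge-dominated; they are computed, not rejected.
    """
    t, x, dt_ms = _as_series(t, x)
    if fmin <= 0 or fmax <= fmin:
        raise ValueError("need 0 < fmin < fmax")
    sfreq = 1000.0 / dt_ms
    if fmax > sfreq / 2:
        raise ValueError("fmax exceeds the Nyquist frequency")
    if t[-1] - t[0] < 1000.0 / fmax:
        raise ValueError("series shorter than one wavelet support in the band")
    freqs = np.arange(fmin, fmax + df / 2, df)
    y = x - x.mean() if detrend else x
    n = y.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    Y = np.fft.fft(y, nfft)
    power = np.empty((freqs.size, n))
    for i, f0 in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * math.pi * f0)        # s
        half = min(int(5 * sigma_t * sfreq), n - 1)
        tt = np.arange(-half, half + 1) / sfreq          # s
        w = np.exp(2j * math.pi * f0 * tt) * np.exp(-(tt ** 2) / (2 * sigma_t ** 2))
        w /= np.abs(w).sum() / 2.0   # unit sinusoid -> |W| ~ 1/2 at f0
        W = np.fft.fft(w, nfft)
        conv = np.fft.ifft(Y * W)[half:half + n]
        power[i] = np.abs(conv) ** 2
    return Spectrogram(t=t, f=freqs, power=power)


def welch_periodogram(t, x, nfft: int | None = None,
                      nperseg: int | None = None,
                      detrend: str = "constant") -> Periodogram:
    """Hann-tapered Welch periodogram.

    By default a single segment spans the entire window (the stationary
    estimate used for 500 ms analysis intervals), zero-padded for a fine
    frequency grid.  Power uses 'spectrum' scaling, so a sinusoid of
    amplitude A peaks near A^2/2 (signal units squared).
    """
    t, x, dt_ms = _as_series(t, x)
    fs = 1000.0 / dt_ms
    nperseg = x.size if nperseg is None else min(nperseg, x.size)
    if nfft is None:
        nfft = max(nperseg, int(2 ** np.ceil(np.log2(nperseg * 8))))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, nfft=nfft,
                     detrend=detrend, scaling="spectrum")
    return Periodogram(f=f, power=p)


# ---------------------------------------------------------------------------
# extrema and slope ratio
# ---------------------------------------------------------------------------

@dataclass
class Extrema:
    """Strictly alternating peak/trough sequence of an oscillation."""

    times: np.ndarray      # ms
    values: np.ndarray
    kinds: np.ndarray      # +1 peak, -1 trough

    @property
    def n_peaks(self) -> int:
        return int(np.sum(self.kinds == 1))

    @property
    def n_cycles(self) -> int:
        """Complete trough-peak-trough cycles."""
        n = 0
        k = self.kinds
        for i in range(len(k) - 2):
            if k[i] == -1 and k[i + 1] == 1 and k[i + 2] == -1:
                n += 1
        return n


def find_extrema(t, x, prominence_frac: float = 0.10) -> Extrema:
    """Prominence-filtered local maxima and minima, alternation enforced.

    The prominence threshold is ``prominence_frac`` times the interquartile
    range of the series, which suppresses small high-frequency ripple while
    keeping one peak per cycle of the dominant rhythm.  Between two
    same-kind extrema the more extreme one is kept.
    """
    t, x, _ = _as_series(t, x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    prom = prominence_frac * iqr if iqr > 0 else None
    pk, _ = sps.find_peaks(x, prominence=prom)
    tr, _ = sps.find_peaks(-x, prominence=prom)
    idx = np.concatenate([pk, tr])
    kind = np.concatenate([np.ones(pk.size, int), -np.ones(tr.size, int)])
    order = np.argsort(idx, kind="stable")
    idx, kind = idx[order], kind[order]
    # enforce alternation: among runs of equal kind keep the most extreme
    keep_idx, keep_kind = [], []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            if (k == 1 and x[i] > x[keep_idx[-1]]) or \
               (k == -1 and x[i] < x[keep_idx[-1]]):
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
            keep_kind.append(k)
    keep_idx = np.asarray(keep_idx, int)
    return Extrema(times=t[keep_idx], values=x[keep_idx],
                   kinds=np.asarray(keep_kind, int))


@dataclass
class SlopeRatioResult:
    """Per-cycle slope ratios and their summary statistics.

    ``phi`` is the mean of ``phi_i = |rise slope| / |fall slope|`` over
    trough-peak-trough cycles; values below 1 indicate waveforms whose
    falling phase is steeper than the rising phase (inhibition-paced
    spiking rhythms), values above 1 the converse (drive-relaxation
    waveforms).  ``Phi`` is defined (non-NaN) only for >= 3 cycles.
    """

    phi_i: np.ndarray
    extrema: Extrema
    alpha: float = 0.05

    @property
    def n_cycles(self) -> int:
        return self.phi_i.size

    @property
    def phi(self) -> float:
        return float(np.mean(self.phi_i)) if self.n_cycles >= 3 else float("nan")

    @property
    def se(self) -> float:
        if self.n_cycles < 3:
            return float("nan")
        return float(np.std(self.phi_i, ddof=1) / np.sqrt(self.n_cycles))

    def p_value(self, alternative: str = "auto") -> float:
        """One-sided one-sample t-test of phi_i against 1."""
        if self.n_cycles < 3:
            return float("nan")
        if alternative == "auto":
            alternative = "less" if self.phi < 1 else "greater"
        return float(sstats.ttest_1samp(self.phi_i, 1.0,
                                        alternative=alternative).pvalue)


def slope_ratio(extrema: Extrema) -> SlopeRatioResult:
    """Slope ratio from an alternating extrema sequence.

    For each trough -> peak -> trough cycle, ``m_rise`` and ``m_fall`` are
    the linear slopes between the extrema; ``phi_i = |m_rise| / |m_fall|``.
    Rejects non-alternating sequences.
    """
    k = extrema.kinds
    if np.any(k[1:] == k[:-1]):
        raise ValueError("extrema sequence is not alternating")
    phis = []
    tt, vv = extrema.times, extrema.values
    for i in range(len(k) - 2):
        if k[i] == -1 and k[i + 1] == 1 and k[i + 2] == -1:
            rise = (vv[i + 1] - vv[i]) / (tt[i + 1] - tt[i])
            fall = (vv[i + 2] - vv[i + 1]) / (tt[i + 2] - tt[i + 1])
            if fall != 0:
                phis.append(abs(rise) / abs(fall))
    return SlopeRatioResult(phi_i=np.asarray(phis), extrema=extrema)


#: Default pre-filtering applied to current-dipole series before extrema
#: detection.  Spiking rhythms superimpose ~1 ms action-potential transients
#: on the cycle-scale waveform; a running median removes such brief spikes
#: exactly while leaving monotone ramps (the rise/fall slopes the statistic
#: quantifies) untouched, and a light Gaussian then suppresses residual
#: sample-scale ripple.  A plain Gaussian wide enough to kill the transients
#: would also blunt the sharp rising edge of drive-relaxation waveforms and
#: bias their slope ratio toward 1.
SLOPE_RATIO_MEDIAN_MS = 2.5
SLOPE_RATIO_SMOOTH_MS = 0.5


def slope_ratio_of_series(t, x, prominence_frac: float = 0.10,
                          smooth_sigma_ms: float = SLOPE_RATIO_SMOOTH_MS,
                          median_ms: float = SLOPE_RATIO_MEDIAN_MS,
                          ) -> SlopeRatioResult:
    """Extrema detection followed by slope-ratio computation.

    The series is pre-filtered with a running median of width ``median_ms``
    followed by a Gaussian kernel of width ``smooth_sigma_ms`` (pass 0 to
    disable either stage); the series must be uniformly sampled for the
    filters to apply.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if t.size >= 2:
        dt = t[1] - t[0]
        if median_ms > 0:
            k = int(round(median_ms / dt))
            x = median_filter(x, size=k + 1 - k % 2, mode="nearest")
        if smooth_sigma_ms > 0:
            x = gaussian_filter1d(x, smooth_sigma_ms / dt)
    return slope_ratio(find_extrema(t, x, prominence_frac))


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

@dataclass
class Histogram:
    edges: np.ndarray      # ms, len n_bins + 1
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _histogram(events, bin_ms: float, window) -> Histogram:
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    ev = np.sort(np.asarray(events, float).ravel())
    if window is None:
        if ev.size == 0:
            window = (0.0, bin_ms)
        else:
            window = (math.floor(ev.min() / bin_ms) * bin_ms,
                      math.ceil((ev.max() + 1e-9) / bin_ms) * bin_ms)
    lo, hi = window
    n_bins = max(1, int(round((hi - lo) / bin_ms)))
    edges = lo + np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(ev, edges)
    return Histogram(edges=edges, counts=counts)


def spike_histogram(spike_times, bin_ms: float = 1.0, window=None) -> Histogram:
    """Population spike histogram with 1 ms default bins."""
    return _histogram(spike_times, bin_ms, window)


def psth(event_times, bin_ms: float = 5.0, window=None) -> Histogram:
    """Peristimulus time histogram of discrete events, 5 ms default bins."""
    return _histogram(event_times, bin_ms, window)


# ---------------------------------------------------------------------------
# high-gamma epochs
# ---------------------------------------------------------------------------

@dataclass
class HighGammaEpoch:
    """One transient high-gamma event: 50 ms window centred on max P_M."""

    t_max: float           # ms
    f: float               # Hz
    power: float           # P_M at the maximum
    window: tuple[float, float]


def find_high_gamma_epochs(spec: Spectrogram, band=(100.0, 150.0),
                           window_ms: float = 50.0,
                           threshold_frac: float = 0.5) -> list[HighGammaEpoch]:
    """Transient epochs of band-limited (default 100-150 Hz) spectral power.

    Local maxima of the within-band power envelope exceeding
    ``threshold_frac`` of its global maximum are reported, separated by at
    least ``window_ms`` so the 50 ms windows do not overlap.
    """
    sub = spec.band(*band)
    if sub.f.size == 0:
        raise ValueError("spectrogram does not cover the requested band")
    env = sub.power.max(axis=0)
    if not np.any(env > 0):
        return []
    dt = float(np.mean(np.diff(sub.t)))
    dist = max(1, int(round(window_ms / dt)))
    peaks, _ = sps.find_peaks(env, height=threshold_frac * env.max(),
                              distance=dist)
    out = []
    lo_t, hi_t = float(sub.t[0]), float(sub.t[-1])
    for j in peaks:
        i = int(np.argmax(sub.power[:, j]))
        t_max = float(sub.t[j])
        half = window_ms / 2.0
        out.append(HighGammaEpoch(
            t_max=t_max, f=float(sub.f[i]), power=float(sub.power[i, j]),
            window=(max(lo_t, t_max - half), min(hi_t, t_max + half))))
    return out
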