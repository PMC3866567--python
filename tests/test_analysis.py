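"""Analysis layer against constructed fixtures with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammacd import (FixtureSpec, find_extrema, find_high_gamma_epochs,
                     make_fixture, morlet_spectrogram, psth, slope_ratio,
                     slope_ratio_of_series, spike_histogram, welch_periodogram)

SETTINGS = dict(max_examples=25, deadline=None)


def _sin(f=50.0, noise=0.0, seed=0, duration=500.0):
    return make_fixture(FixtureSpec("sinusoid", {"f_hz": f}, noise_sd=noise,
                                    seed=seed, duration_ms=duration))


# ---------------------------------------------------------------------------
# spectral estimates vs FFT oracle
# ---------------------------------------------------------------------------

def test_welch_peak_matches_fft_oracle():
    """Welch peak within one frequency bin of a plain-FFT oracle for tones."""
    fx = _sin(f=52.0)
    pg = welch_periodogram(fx.t, fx.x)
    f_pk, _ = pg.peak(1.0, 150.0)
    # FFT oracle on the raw series
    dt_s = (fx.t[1] - fx.t[0]) / 1000.0
    spec = np.abs(np.fft.rfft(fx.x - fx.x.mean())) ** 2
    f_fft = np.fft.rfftfreq(fx.x.size, dt_s)[np.argmax(spec)]
    df_welch = pg.f[1] - pg.f[0]
    df_fft = 1000.0 / (fx.t[-1] - fx.t[0])
    assert abs(f_pk - f_fft) <= df_welch + df_fft
    assert abs(f_pk - 52.0) <= df_welch + df_fft


def test_welch_amplitude_scaling():
    """Spectrum scaling: amplitude-A sinusoid peaks near A^2/2."""
    fx = _sin(f=50.0)
    a = fx.truth["amplitude"]
    _, p = welch_periodogram(fx.t, fx.x).peak(40.0, 60.0)
    # Hann-tapered single segment spreads power over a few bins
    assert 0.1 * a ** 2 / 2 < p <= 1.1 * a ** 2 / 2


def test_morlet_peak_frequency():
    fx = _sin(f=52.0)
    _, f_pk, _ = morlet_spectrogram(fx.t, fx.x).peak
    assert abs(f_pk - 52.0) <= 1.0


def test_tone_mixture_dominant_component():
    fx = make_fixture(FixtureSpec("tone_mixture",
                                  {"components": [(38.0, 1e-2), (95.0, 4e-3)]}))
    f_pk, _ = welch_periodogram(fx.t, fx.x).peak(1.0, 150.0)
    assert abs(f_pk - fx.truth["dominant_f_hz"]) <= 1.0


def test_morlet_rejects_bad_band():
    fx = _sin()
    with pytest.raises(ValueError):
        morlet_spectrogram(fx.t, fx.x, fmin=10.0, fmax=5.0)
    with pytest.raises(ValueError):
        morlet_spectrogram(fx.t, fx.x, fmax=1e6)   # beyond Nyquist


def test_nonuniform_sampling_rejected():
    t = np.array([0.0, 1.0, 3.0, 4.0])
    with pytest.raises(ValueError, match="uniform"):
        welch_periodogram(t, np.zeros_like(t))


# ---------------------------------------------------------------------------
# extrema and slope ratio
# ---------------------------------------------------------------------------

def test_extrema_alternate_and_count_cycles():
    fx = _sin(f=40.0, duration=500.0)
    ex = find_extrema(fx.t, fx.x)
    assert np.all(ex.kinds[1:] != ex.kinds[:-1])
    assert 18 <= ex.n_cycles <= 20          # 40 Hz for 500 ms


def test_slope_ratio_exact_on_triangle():
    """Phi oracle: asymmetric triangle gives exactly fall/rise per cycle."""
    fx = make_fixture(FixtureSpec("asym_triangle",
                                  {"rise_ms": 15.0, "fall_ms": 5.0}))
    sr = slope_ratio_of_series(fx.t, fx.x, smooth_sigma_ms=0.0, median_ms=0.0)
    assert sr.n_cycles >= 3
    np.testing.assert_allclose(sr.phi_i, fx.truth["phi"], rtol=1e-6)
    assert sr.p_value() < 1e-6              # decisively below 1


def test_slope_ratio_sinusoid_near_one():
    fx = _sin(f=50.0)
    sr = slope_ratio_of_series(fx.t, fx.x, smooth_sigma_ms=0.0, median_ms=0.0)
    assert sr.phi == pytest.approx(1.0, abs=1e-3)


@settings(**SETTINGS)
@given(scale=st.floats(1e-3, 1e3), shift=st.floats(-1.0, 1.0),
       rise=st.floats(4.0, 20.0), fall=st.floats(4.0, 20.0))
def test_slope_ratio_amplitude_and_offset_invariant(scale, shift, rise, fall):
    fx = make_fixture(FixtureSpec("asym_triangle",
                                  {"rise_ms": rise, "fall_ms": fall}))
    a = slope_ratio_of_series(fx.t, fx.x, smooth_sigma_ms=0.0, median_ms=0.0)
    b = slope_ratio_of_series(fx.t, scale * fx.x + shift, smooth_sigma_ms=0.0, median_ms=0.0)
    assert b.phi == pytest.approx(a.phi, rel=1e-9)


@settings(**SETTINGS)
@given(rise=st.floats(5.0, 20.0), fall=st.floats(5.0, 20.0))
def test_slope_ratio_time_reversal_inverts(rise, fall):
    fx = make_fixture(FixtureSpec("asym_triangle",
                                  {"rise_ms": rise, "fall_ms": fall}))
    fwd = slope_ratio_of_series(fx.t, fx.x, smooth_sigma_ms=0.0, median_ms=0.0)
    rev = slope_ratio_of_series(fx.t, fx.x[::-1], smooth_sigma_ms=0.0, median_ms=0.0)
    assert rev.phi == pytest.approx(1.0 / fwd.phi, rel=0.05)


def test_slope_ratio_rejects_nonalternating():
    from gammacd.analysis import Extrema
    ex = Extrema(times=np.array([0.0, 1.0, 2.0]),
                 values=np.array([1.0, 2.0, 0.5]),
                 kinds=np.array([1, 1, -1]))
    with pytest.raises(ValueError, match="alternating"):
        slope_ratio(ex)


def test_slope_ratio_undefined_below_three_cycles():
    fx = _sin(f=50.0, duration=45.0)   # ~2 complete cycles
    sr = slope_ratio_of_series(fx.t, fx.x, smooth_sigma_ms=0.0, median_ms=0.0)
    assert sr.n_cycles < 3
    assert np.isnan(sr.phi) and np.isnan(sr.se) and np.isnan(sr.p_value())


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def test_spike_histogram_counts_and_bins():
    ev = np.array([0.2, 0.7, 1.5, 3.9])
    h = spike_histogram(ev, bin_ms=1.0, window=(0.0, 4.0))
    np.testing.assert_array_equal(h.counts, [2, 1, 0, 1])
    assert h.total == 4
    np.testing.assert_allclose(h.centers, [0.5, 1.5, 2.5, 3.5])


def test_psth_default_bin():
    ev = np.array([1.0, 4.0, 6.0])
    h = psth(ev, window=(0.0, 10.0))
    np.testing.assert_array_equal(h.counts, [2, 1])


def test_histogram_rejects_nonpositive_bin():
    with pytest.raises(ValueError):
        spike_histogram([1.0], bin_ms=0.0)


# ---------------------------------------------------------------------------
# high-gamma epochs
# ---------------------------------------------------------------------------

def test_high_gamma_epochs_detected_at_known_times():
    fx = make_fixture(FixtureSpec("gated_transient",
                                  {"f_hz": 120.0, "at_ms": [150.0, 350.0],
                                   "n_cycles": 2.0, "amplitude": 2e-2}))
    spec = morlet_spectrogram(fx.t, fx.x)
    eps = find_high_gamma_epochs(spec)
    assert len(eps) == 2
    for ep, truth_t in zip(eps, [150.0, 350.0]):
        assert abs(ep.t_max - truth_t) < 10.0
        assert 100.0 <= ep.f <= 150.0
        assert ep.window[1] - ep.window[0] == pytest.approx(50.0, abs=1e-9)


def test_high_gamma_band_weak_in_pure_low_gamma():
    """A pure 52 Hz tone leaves only leakage in the 100-150 Hz band."""
    fx = _sin(f=52.0)
    spec = morlet_spectrogram(fx.t, fx.x)
    hg = spec.band(100.0, 150.0).power.max()
    assert hg < 1e-2 * spec.peak[2]
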