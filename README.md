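# gammacd

A laminar neocortical network model of gamma-band **current dipole (CD)**
signals. The package simulates three distinct generators of gamma
(30–80 Hz) rhythms in reduced compartmental pyramidal-cell networks and
quantifies the resulting current-source waveforms with the spectral and
slope-ratio statistics needed to tell the mechanisms apart:

1. **Strong PING** — all layer-5 pyramidal cells are driven
   suprathreshold by tonic current and fire on every cycle; the rhythm is
   paced by reciprocal pyramidal → basket excitation and basket → pyramidal
   GABA<sub>A</sub> inhibition (5 ms decay), producing a ~36 Hz population
   oscillation with large (~0.3 nAm per 100 cells) dipole deflections.
2. **Weak PING** — pyramidal cells receive independent Poisson synaptic
   noise and fire sparsely (~10 Hz per cell), yet the pooled
   pyramidal–interneuron loop still produces a coherent ~50 Hz dipole
   rhythm, an order of magnitude smaller in amplitude.
3. **Subthreshold driven gamma** — gamma-periodic bursts of weak (40 pS)
   excitatory events arrive on the proximal dendrites (and optionally the
   distal apical tuft, lagged by 5 ms) without ever bringing a cell to
   threshold; the dipole rhythm is inherited from the exogenous drive.

## Why the waveform matters

All three regimes can produce a spectral peak in the gamma band, so power
alone cannot identify the generator. Two waveform statistics can:

- **Slope ratio Φ** — the mean over trough–peak–trough cycles of
  |rising slope| / |falling slope| of the CD waveform. PING rhythms have a
  *sharp falling phase* (the synchronous volley and ensuing inhibition pull
  the dipole down quickly), giving Φ < 1. Subthreshold drive-relaxation
  waveforms rise sharply with each input burst and decay slowly, giving
  Φ > 1.
- **Sensitivity to input dispersion** — for driven rhythms, widening the
  per-cycle Gaussian jitter of the input bursts (σ 2.5 → 5.0 ms) collapses
  spectral power (~80 % for proximal drive, ~35 % for a lagged distal
  drive), whereas PING power is insensitive to this manipulation.

The dipole forward model also explains why layer 5 dominates the signal:
the CD weights axial currents by their projection on the apical axis, and
the L5 apical dendrite is 2.21× longer than its L2/3 counterpart, yielding
a ~3-fold larger maximal dipole at matched firing rates.

## Worked example

Run the shipped strong-PING scenario and inspect the summary statistics:

```python
from gammacd import load_shipped, run_scenario

bundle = run_scenario(load_shipped("fig2a_strong_ping"))
st = bundle.stats["L5"]
print(f"cycle rate      : {st['n_cycles'] / 0.5:.0f} Hz "
      f"({st['n_cycles']} cycles / 500 ms)")
print(f"max |CD|        : {st['max_abs_cd_nAm']:.3f} nAm")
print(f"slope ratio Phi : {st['phi']:.2f}")
print(f"mean E rate     : {st['e_rate_mean_hz']:.1f} Hz")
```

Output (one ~28 s simulation of 135 cells for 550 ms on one CPU):

```
cycle rate      : 34 Hz (17 cycles / 500 ms)
max |CD|        : 0.414 nAm
slope ratio Phi : 0.09
mean E rate     : 36.0 Hz
```

Every cell fires on every population volley (18 volleys in the 500 ms
window → E rate 36 Hz; the extrema detector resolves 17 complete
trough–peak–trough CD cycles of those 18 volleys, since the cycle
flanking the window edge is dropped). The dipole deflections are large
and Φ ≪ 1: a sawtooth-like waveform with a sharp falling phase, the PING
signature. (The strong-PING volleys are so brief
that the Welch/Morlet spectral peak lands on a harmonic near 70 Hz; use
the cycle count for the fundamental.)

The same from the command line, plus a parameter sweep over the proximal
input dispersion of the subthreshold regime:

```sh
gammacd simulate --config fig2a_strong_ping --out out/
gammacd sweep --config fig6a_prox50_sp2.5 \
              --param drives.proximal.sigma_ms --values 2.5,5.0,7.5
gammacd analyze --input out/cd_L5.txt --stats phi,welch
```

`gammacd simulate` writes per-layer CD text series, a spike list, a JSON
summary, and a single HDF5 bundle embedding the configuration snapshot and
its hash for provenance.

## Shipped scenarios

| name | regime |
| --- | --- |
| `fig2a_strong_ping` | L5 strong PING (tonic drive, no I→I) |
| `fig2b_weak_ping`, `fig3_weak_ping` | L5 weak PING (Poisson noise; `fig3` uses the reduced-conductance variant) |
| `fig4_weak_ping_high_gamma` | weak PING analyzed for transient high-gamma (100–150 Hz) epochs |
| `fig5_l2_weak_ping` | matched L2/3 weak PING (laminar amplitude comparison) |
| `fig6a/b/c_prox50_sp*` | subthreshold 50 Hz proximal drive, σ<sub>p</sub> = 2.5 / 5.0 / 7.5 ms |
| `fig7b_prox80_sp2.5`, `fig7c_prox100_sp2.5` | subthreshold proximal drive at 80 / 100 Hz |
| `fig8a/b/c_proxdist_sd*` | combined proximal + lagged distal drive, σ<sub>d</sub> = 2.5 / 5.0 / 7.5 ms |

All scenarios run 550 ms at dt = 0.025 ms and analyze the final 500 ms.

## Package layout

- `gammacd.cells` — reduced compartmental L2/3 / L5 pyramidal and basket
  cell models (Hodgkin–Huxley-style channels, cable segments).
- `gammacd.network` — populations on a 10×10 grid, distance-scaled
  synapses, regime parameter table, the simulation engine front end.
- `gammacd.drives` — tonic, Poisson, and rhythmic Gaussian-burst drives.
- `gammacd.dipole` — apical-axis current-dipole forward model, baseline
  renormalization, network-size extrapolation.
- `gammacd.analysis` — Morlet spectrogram, Welch periodogram, extrema and
  slope ratio, spike histograms, high-gamma epoch detection.
- `gammacd.scenarios` / `gammacd.io` / `gammacd.cli` — config-driven runs,
  sweeps, HDF5/text products, command-line interface.
- `gammacd.fixtures` — synthetic waveforms with exact ground truth used to
  test the analysis layer independently of the simulator.

See `docs/methods.md` for modeling choices, units, and calibration notes.
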