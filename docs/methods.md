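# Methods and modeling notes

This document records the concrete modeling choices, unit conventions, and
calibration scope behind `gammacd`. The shape of the emergent behaviour —
oscillation frequencies, slope ratios, relative amplitudes, and their
responses to the documented manipulations — is the validated surface of
the package; individual biophysical constants are calibrated means to that
end and should not be read as measurements.

## Cells

Three cell classes (`gammacd.cells`, parameters in
`src/gammacd/data/cell_parameters.yaml`):

- **L2/3 pyramidal** — 8 compartments (soma, apical trunk/1/tuft, one
  oblique, three basals), C<sub>m</sub> 0.62 µF/cm².
- **L5 pyramidal** — 9 compartments with a longer apical axis; the summed
  apical-axis extent (102 + 463.92 + 463.92 + 305 = 1334.84 µm) is exactly
  2.21× the L2/3 extent (604 µm). C<sub>m</sub> 0.85 µF/cm². Adds Ca
  (HVA + T-type), h, and K<sub>Ca</sub> currents with a first-order
  calcium pool.
- **Basket (fast-spiking) interneuron** — single 15 × 10 µm compartment
  with fast Na/K only, small capacitance (0.5 µF/cm²), giving the brief
  spikes and short membrane time constant of fast-spiking cells.

Compartments longer than 100 µm are split into two equal cable segments.
Axial coupling conductances are computed between segment centres from the
axial resistivity (200 Ω·cm). Channel kinetics use canonical
Traub/Mainen-lineage rate functions with the usual temperature adjustment
factors baked into the gate time constants.

**Dendritic Na profile (L5).** Na density is strongly reduced along the
apical axis (40 mS/cm² on trunk/apical/tuft vs 250 mS/cm² on soma, basals,
and the oblique). Physically this is weak backpropagation of the somatic
spike into the apical tree. Practically it matters because the dipole only
sees the apical axis (see below): with uniform dendritic Na, every somatic
spike injected a tall ~1 ms transient into the CD which swamped the
cycle-scale waveform; keeping the basals/obliques excitable preserves
recruitment by proximal drive while the CD waveform stays smooth.

## Synapses

Two-exponential conductances, normalized so a unit-weight event peaks at
its nominal conductance. All conductances are in µS; delivery delay is
1 ms everywhere.

| synapse | rise / decay (ms) | reversal |
| --- | --- | --- |
| AMPA (default, onto pyramidal) | 0.5 / 5.0 | 0 mV |
| AMPA onto basket cells | 0.5 / 2.5 | 0 mV |
| AMPA of rhythmic (burst) drives | 0.5 / 8.5 | 0 mV |
| AMPA of Poisson (noise) drives | 0.5 / 9.0 | 0 mV |
| GABA<sub>A</sub> | 0.5 / 5.0 | −80 mV |

The faster AMPA decay onto fast-spiking cells reflects their
GluA4-dominated receptors and is what lets the basket volley track the
pyramidal volley tightly enough for ~36 Hz strong PING. The slower decay
of exogenous burst-drive synapses (thalamocortical-like) keeps the
proximal depolarization elevated when the 5 ms-lagged distal dip arrives,
which is what places the combined-drive slope ratio just above 1. The
still-slower Poisson-drive decay is a lumped AMPA+NMDA-like conductance:
it sustains depolarization between sparse noise events, so the weak-PING
rhythm is paced by the decay of pooled inhibition (~50 Hz) rather than
locking to individual event arrivals (which would pin the rhythm near the
per-cell event rate).

The engine supports per-segment AMPA kinetics
(`Network.set_ampa_kinetics`); drive attachment uses it to give burst-drive
target segments the drive kinetics without touching recurrent synapses.

## Network

Each simulated layer holds 100 pyramidal cells on a 10 × 10 grid and 35
baskets on an interleaved grid. Connectivity is all-to-all within the
allowed motifs (E→I AMPA on the basket soma, I→E GABA<sub>A</sub> on the
pyramidal soma, I→I where the regime enables it; no E→E, no interlaminar
synapses). Weights scale with planar distance as exp(−(d/λ)²) with
per-class space constants λ<sub>EI</sub> = 3, λ<sub>IE</sub> = 30,
λ<sub>II</sub> = 20 grid units: pyramidal→basket excitation is local while
basket output blankets the grid. λ<sub>IE</sub> doubles as the calibration
knob for aggregate somatic inhibition, which sets the decay-limited
weak-PING period.

The regime table (`gammacd.network.TABLE1`) carries the per-connection
conductances: strong PING (g<sub>EI</sub> 6·10⁻⁵, g<sub>IE</sub> 0.3,
g<sub>II</sub> 0, tonic I_app 6), L5 weak PING (9.1·10⁻⁴, 8·10⁻²,
7.5·10⁻³, Poisson λ 40 Hz at 10⁻² µS, with a 0.75·10⁻² figure variant),
and L2/3 weak PING (1.2·10⁻³, 7·10⁻³, 10⁻², λ 140 Hz at 0.8·10⁻³ µS).

**Tonic drive units.** Regime-table I_app values are model units; one unit
is `i_app_unit_nA` = 3.5 nA of somatic current, so the strong-PING row
injects 21 nA. This single constant calibrates the strong-PING cycle count
and amplitude and does not interact with the (untonic) weak-PING regimes.

## Drives

- **TonicDrive** — constant somatic current on every pyramidal cell.
- **PoissonDrive** — independent per-cell Poisson AMPA trains; the
  "proximal" target delivers each event simultaneously to the apical
  oblique and both distal basal compartments.
- **RhythmicBurstDrive** — per cycle, 10 events drawn from
  Normal(cycle mean, σ²), identical across cells, 40 pS each; proximal
  targets as above, distal targets the first apical-tuft segment; distal
  cycle means lag proximal ones by 5 ms. All events pass through the 1 ms
  synaptic delay. With these conductances no cortical cell reaches spike
  threshold (asserted in the tests).

All stochastic drives are bit-reproducible given their seed; scenario
seeds fan out to per-drive seeds through `numpy.random.SeedSequence`.

## Current dipole

For every non-root segment the axial current from its parent,
g<sub>ax</sub>(v<sub>parent</sub> − v), is weighted by the segment's
signed apical-axis projection z (µm) and summed over pyramidal cells:
(mV/MΩ)·µm = 10⁻⁶ nAm. Oblique dendrites run parallel to the laminae
(z = 0) and contribute nothing; basal dendrites descend at 45° and enter
with z = −length/√2; basket cells are excluded. This forward model is
checked against a brute-force oracle at 10⁻¹² relative tolerance, and a
passive (channels-zeroed) configuration of the full integrator is checked
against the exact matrix-exponential solution of the linear cable system
to ≤ 0.5 % RMS.

## Analysis

- **Morlet spectrogram** (1–150 Hz, 11-cycle wavelets — at constant Q the
  bandwidth f/11 is narrow enough that noisy gamma peaks are not biased
  downward by the broadband background) and **Welch
  periodogram** (Hann taper, single segment spanning the 500 ms analysis
  window, zero-padded). Peak locations agree with a plain-FFT oracle to
  ±1 bin on pure tones.
- **Slope ratio Φ**: prominence-filtered extrema (threshold 0.1 × IQR,
  alternation enforced), per-cycle Φ<sub>i</sub> = |rise|/|fall| over
  trough–peak–trough cycles, mean ± s.e. with a one-sided t-test against
  1. Φ is exact on constructed asymmetric triangles.
- **Pre-filtering**: `slope_ratio_of_series` applies a 2.5 ms running
  median followed by a 0.5 ms Gaussian kernel (`SLOPE_RATIO_MEDIAN_MS`,
  `SLOPE_RATIO_SMOOTH_MS`; pass 0 to disable either) before extrema
  detection. Spiking regimes superimpose ~1 ms action-potential transients
  on the cycle-scale CD; the median removes such brief spikes exactly
  while leaving monotone ramps untouched, and the light Gaussian clears
  residual sample-scale ripple. A Gaussian wide enough to kill the
  transients on its own would also blunt the sharp rising edge of
  drive-relaxation waveforms and bias their slope ratio toward 1.
- **High-gamma epochs**: local maxima of 100–150 Hz Morlet power above
  half the band maximum, reported with non-overlapping 50 ms windows.

## Simulation protocol

550 ms at dt = 0.025 ms (exponential-Euler gates, Hines-ordered implicit
solve for the cable equation); the first 50 ms are discarded and all
statistics use the 500 ms analysis window. Stochastic quantities are
averaged over ≥ 5 seeds. A single 550 ms run of 135 cells takes ~28 s on
one CPU core (numba-compiled engine).

## Calibration scope and limitations

Printed, structural facts (population sizes, regime-table conductances,
the 2.21 apical ratio, 5 ms GABA<sub>A</sub> decay, burst-drive protocol,
550 ms / dt 0.025 protocol) are taken as fixed. Constants the source
lineage does not print — channel densities, space constants beyond
λ<sub>EI</sub> = 3, AMPA decays by target class, the tonic-unit scale —
were calibrated so the emergent quantities land in their published bands;
the bands themselves were never touched. Consequences to keep in mind:

- Absolute CD amplitudes are only constrained to a factor of ~2; use
  relative amplitudes (e.g. the L5/L2 ratio) for inference.
- The basket model is a minimal fast-spiking caricature; it is not meant
  to reproduce interneuron biophysics beyond volley timing.
- Baseline renormalization constants in `gammacd.dipole` are tied to the
  default 100-cell populations (they scale linearly with `n_pyr`).
- The strong-PING regime is fully synchronous and deterministic; its
  frequency is reported by cycle counting (18 cycles / 500 ms = 36 Hz in
  the shipped configuration). The CD waveform is strongly non-sinusoidal
  (brief synchronous volleys), so the Welch/Morlet spectral peak sits on a
  harmonic of the cycle rate (~70 Hz) rather than the fundamental; use the
  cycle count, not the spectral peak, for the strong-PING frequency.
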