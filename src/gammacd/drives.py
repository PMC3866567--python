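"""Exogenous drives: tonic current, Poisson synaptic noise, rhythmic bursts.

Three input classes generate the regimes studied with this model:

* ``TonicDrive`` — constant somatic current to the pyramidal cells
  (strong PING);
* ``PoissonDrive`` — independent Poisson trains of AMPA events onto each
  pyramidal soma (weak PING);
* ``RhythmicBurstDrive`` — gamma-periodic bursts of 10 Gaussian-jittered
  40 pS AMPA events per cycle, identical across cells, targeting either the
  proximal pattern (apical oblique + both distal basal compartments) or the
  distal apical tuft.  Distal cycle means lag proximal ones by 5 ms; all
  synaptic events are delivered with a 1 ms synaptic delay.

All stochastic drives are reproducible bit-for-bit given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine as _engine
from .network import Network, CellRef

PROXIMAL_TARGETS = ("apical_oblique", "basal_2", "basal_3")
DISTAL_TARGET = "apical_tuft"


@dataclass(frozen=True)
class TonicDrive:
    """Constant applied current to pyramidal somata (regime-table ``I_app``,
    model current units; one unit = ``i_app_unit_nA`` nA)."""

    i_app: float
    layer: str | None = None          # None: every simulated layer
    target: str = "soma"
    population: str = "pyramidal"


@dataclass(frozen=True)
class PoissonDrive:
    """Independent Poisson AMPA event trains onto each pyramidal soma."""

    rate_hz: float                    # lambda_pois
    g_max: float                      # uS per event
    seed: int = 0
    layer: str | None = None
    target: str = "soma"
    population: str = "pyramidal"
    per_cell_independent: bool = True

    def __post_init__(self):
        if self.rate_hz < 0:
            raise ValueError("Poisson rate must be nonnegative")
        if self.g_max < 0:
            raise ValueError("g_max must be nonnegative")


@dataclass(frozen=True)
class RhythmicBurstDrive:
    """Gamma-periodic Gaussian event bursts, identical for all cells."""

    input_class: str                  # "proximal" | "distal"
    f: float                          # Hz
    sigma: float                      # ms (sigma_p or sigma_d)
    events_per_cycle: int = 10
    per_event_conductance_pS: float = 40.0
    distal_lag: float = 5.0           # ms, lag of distal cycle means
    synaptic_delay: float = 1.0       # ms
    seed: int = 0
    layer: str = "L5"
    population: str = "pyramidal"

    def __post_init__(self):
        if self.input_class not in ("proximal", "distal"):
            raise ValueError("input_class must be 'proximal' or 'distal'")
        if self.f <= 0:
            raise ValueError("burst frequency must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.population == "basket":
            raise ValueError("rhythmic burst drives target pyramidal cells only")


def sample_poisson_events(drive: PoissonDrive, n_cells: int,
                          duration: float) -> list[np.ndarray]:
    """Per-cell Poisson event times in [0, duration) ms.

    Streams are independent across cells (spawned from the drive seed) and
    inter-event intervals are exponential with rate ``rate_hz``.
    """
    if drive.rate_hz == 0:
        return [np.empty(0) for _ in range(n_cells)]
    seqs = np.random.SeedSequence(drive.seed).spawn(n_cells)
    rate_per_ms = drive.rate_hz / 1000.0
    out = []
    for sq in seqs:
        rng = np.random.default_rng(sq)
        # draw enough exponential intervals to cover the window
        n_guess = max(16, int(2 * rate_per_ms * duration + 10 *
                              np.sqrt(rate_per_ms * duration + 1)))
        times = np.cumsum(rng.exponential(1.0 / rate_per_ms, n_guess))
        while times.size and times[-1] < duration:
            times = np.concatenate([
                times, times[-1] + np.cumsum(
                    rng.exponential(1.0 / rate_per_ms, n_guess))])
        out.append(times[times < duration])
    return out


def sample_burst_events(drive: RhythmicBurstDrive, duration: float) -> np.ndarray:
    """Event times (ms) of the rhythmic burst drive over [0, duration).

    Cycle means lie at k/f (plus ``distal_lag`` for distal inputs); each
    cycle contributes ``events_per_cycle`` independent draws from
    Normal(mean, sigma^2).  Draws outside [0, duration) are dropped.
    """
    period = 1000.0 / drive.f
    lag = drive.distal_lag if drive.input_class == "distal" else 0.0
    means = np.arange(lag, duration, period)
    rng = np.random.default_rng(drive.seed)
    if drive.sigma == 0:
        events = np.repeat(means, drive.events_per_cycle)
    else:
        events = (means[:, None] + rng.normal(
            0.0, drive.sigma, (means.size, drive.events_per_cycle))).ravel()
    events = events[(events >= 0) & (events < duration)]
    return np.sort(events)


def attach_drives(network: Network, drives, duration: float):
    """Realize drives as events/currents on an existing network.

    Tonic drives add constant somatic current; Poisson and burst drives are
    expanded into synaptic events (with their synaptic delivery delay
    applied) and queued on the target compartments.
    """
    params = network.params
    unit_nA = float(params.get("i_app_unit_nA", 1.0))
    delay = float(params["synapses"]["delivery_delay_ms"])
    for drive in drives:
        if getattr(drive, "population", "pyramidal") == "basket":
            raise ValueError("exogenous drives target pyramidal cells only")
        if isinstance(drive, TonicDrive):
            for cell in _targets(network, drive.layer):
                network.add_tonic_current(cell, drive.target,
                                          drive.i_app * unit_nA)
        elif isinstance(drive, PoissonDrive):
            cells = _targets(network, drive.layer)
            events = sample_poisson_events(drive, len(cells), duration)
            pois_tau = params["synapses"].get("ampa_poisson")
            for cell, times in zip(cells, events):
                comps = (PROXIMAL_TARGETS if drive.target == "proximal"
                         else (drive.target,))
                segs = [cell.comp_segs[c][0] for c in comps]
                if pois_tau is not None:
                    network.set_ampa_kinetics(
                        segs, float(pois_tau["rise_tau_ms"]),
                        float(pois_tau["decay_tau_ms"]))
                w = drive.g_max                  # uS
                for ts in times:
                    for seg in segs:
                        network.add_event(ts + delay, seg, w, _engine.AMPA)
        elif isinstance(drive, RhythmicBurstDrive):
            cells = _targets(network, drive.layer)
            if not cells:
                raise ValueError(f"no pyramidal cells in layer {drive.layer!r}")
            times = sample_burst_events(drive, duration)
            w = drive.per_event_conductance_pS * 1e-6   # pS -> uS
            if drive.input_class == "proximal":
                comps = PROXIMAL_TARGETS
            else:
                comps = (DISTAL_TARGET,)
            drive_tau = params["synapses"].get("ampa_drive")
            for cell in cells:
                for comp in comps:
                    if comp not in cell.comp_segs:
                        raise ValueError(
                            f"cell kind {cell.kind!r} has no compartment {comp!r}")
                    seg = cell.comp_segs[comp][0]
                    if drive_tau is not None:
                        network.set_ampa_kinetics(
                            [seg], float(drive_tau["rise_tau_ms"]),
                            float(drive_tau["decay_tau_ms"]))
                    for ts in times:
                        network.add_event(ts + drive.synaptic_delay, seg, w,
                                          _engine.AMPA)
        else:
            raise TypeError(f"unknown drive type {type(drive).__name__}")
    return network


def _targets(network: Network, layer: str | None) -> list[CellRef]:
    cells = network.cells_of("E", layer)
    if layer is not None and not cells:
        raise ValueError(f"layer {layer!r} not present in this network")
    return cells
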