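"""Synthetic waveforms and event trains with known ground truth.

These fixtures exercise the analysis layer independently of the simulator:
each generated signal carries the exact quantities (frequencies, slope
ratio, event or epoch times) that the analysis operations are expected to
recover.  Amplitudes default to the 1e-2 nAm scale of simulated current
dipoles so the numerics match the real pipeline.

Supported kinds: ``sinusoid``, ``tone_mixture``, ``asym_triangle``,
``gated_transient``, ``poisson_train``, ``burst_train``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default fixture amplitude, nAm scale of simulated dipoles
DEFAULT_AMPLITUDE = 1e-2

SERIES_KINDS = ("sinusoid", "tone_mixture", "asym_triangle", "gated_transient")
EVENT_KINDS = ("poisson_train", "burst_train")
KINDS = SERIES_KINDS + EVENT_KINDS


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic signal or event train.

    ``params`` are kind-specific (see the ``_make_*`` functions); additive
    Gaussian noise of standard deviation ``noise_sd`` is applied to series
    kinds only.
    """

    kind: str
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    duration_ms: float = 500.0
    dt_ms: float = 0.025
    t_start_ms: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"options: {sorted(KINDS)}")
        if self.duration_ms <= 0 or self.dt_ms <= 0:
            raise ValueError("duration and dt must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise s.d. must be nonnegative")


@dataclass
class Fixture:
    """A generated fixture: the signal (or events) plus exact ground truth."""

    spec: FixtureSpec
    t: np.ndarray                   # ms (series kinds) or empty
    x: np.ndarray                   # signal values, or event times (ms)
    truth: dict


def _grid(spec: FixtureSpec) -> np.ndarray:
    n = int(round(spec.duration_ms / spec.dt_ms))
    return spec.t_start_ms + np.arange(n) * spec.dt_ms


def _make_sinusoid(spec: FixtureSpec, t: np.ndarray):
    p = dict(spec.params)
    f = float(p.pop("f_hz", 50.0))
    a = float(p.pop("amplitude", DEFAULT_AMPLITUDE))
    phase = float(p.pop("phase_rad", 0.0))
    if p:
        raise ValueError(f"unknown sinusoid parameters {sorted(p)}")
    if f <= 0:
        raise ValueError("frequency must be positive")
    x = a * np.sin(2 * np.pi * f * (t - t[0]) / 1000.0 + phase)
    return x, {"f_hz": f, "amplitude": a, "phi": 1.0}


def _make_tone_mixture(spec: FixtureSpec, t: np.ndarray):
    p = dict(spec.params)
    comps = p.pop("components", [(40.0, DEFAULT_AMPLITUDE),
                                 (90.0, DEFAULT_AMPLITUDE / 2)])
    if p:
        raise ValueError(f"unknown tone_mixture parameters {sorted(p)}")
    comps = [(float(f), float(a)) for f, a in comps]
    if not comps or any(f <= 0 or a < 0 for f, a in comps):
        raise ValueError("components must be (positive f, nonnegative a) pairs")
    x = np.zeros_like(t)
    for f, a in comps:
        x += a * np.sin(2 * np.pi * f * (t - t[0]) / 1000.0)
    dominant = max(comps, key=lambda fa: fa[1])[0]
    return x, {"components": comps, "dominant_f_hz": dominant}


def _make_asym_triangle(spec: FixtureSpec, t: np.ndarray):
    """Periodic triangle with distinct rise and fall times.

    Ground-truth slope ratio is (amplitude/rise)/(amplitude/fall) =
    fall/rise for every cycle.
    """
    p = dict(spec.params)
    rise = float(p.pop("rise_ms", 15.0))
    fall = float(p.pop("fall_ms", 5.0))
    a = float(p.pop("amplitude", DEFAULT_AMPLITUDE))
    if p:
        raise ValueError(f"unknown asym_triangle parameters {sorted(p)}")
    if rise <= 0 or fall <= 0:
        raise ValueError("rise and fall times must be positive")
    period = rise + fall
    tau = np.mod(t - t[0], period)
    x = np.where(tau < rise, tau / rise, 1.0 - (tau - rise) / fall) * a
    return x, {"rise_ms": rise, "fall_ms": fall, "amplitude": a,
               "phi": fall / rise, "f_hz": 1000.0 / period}


def _make_gated_transient(spec: FixtureSpec, t: np.ndarray):
    """Carrier sinusoid plus one (or more) short high-frequency bursts.

    Emulates the high-gamma epochs embedded in a slower gamma rhythm: each
    transient is ``n_cycles`` cycles of a tone under a Hann gate centred at
    ``at_ms``.
    """
    p = dict(spec.params)
    carrier_f = float(p.pop("carrier_f_hz", 52.0))
    carrier_a = float(p.pop("carrier_amplitude", DEFAULT_AMPLITUDE))
    f = float(p.pop("f_hz", 110.0))
    a = float(p.pop("amplitude", DEFAULT_AMPLITUDE))
    n_cycles = float(p.pop("n_cycles", 1.0))
    at = p.pop("at_ms", 200.0)
    if p:
        raise ValueError(f"unknown gated_transient parameters {sorted(p)}")
    if f <= 0 or n_cycles <= 0:
        raise ValueError("transient frequency and cycle count must be positive")
    centres = np.atleast_1d(np.asarray(at, float))
    x = carrier_a * np.sin(2 * np.pi * carrier_f * (t - t[0]) / 1000.0)
    half = 1000.0 * n_cycles / f / 2.0          # ms
    for c in centres:
        m = np.abs(t - c) <= half
        gate = np.cos(np.pi * (t[m] - c) / (2 * half)) ** 2
        x[m] += a * gate * np.sin(2 * np.pi * f * (t[m] - c) / 1000.0)
    return x, {"carrier_f_hz": carrier_f, "f_hz": f, "at_ms": centres.tolist(),
               "n_cycles": n_cycles, "half_width_ms": half}


def _make_poisson_train(spec: FixtureSpec):
    p = dict(spec.params)
    rate = float(p.pop("rate_hz", 40.0))
    if p:
        raise ValueError(f"unknown poisson_train parameters {sorted(p)}")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    events = []
    t = spec.t_start_ms
    stop = spec.t_start_ms + spec.duration_ms
    while rate > 0:
        t += rng.exponential(1000.0 / rate)
        if t >= stop:
            break
        events.append(t)
    events = np.asarray(events)
    return events, {"rate_hz": rate, "n_events": int(events.size)}


def _make_burst_train(spec: FixtureSpec):
    p = dict(spec.params)
    f = float(p.pop("f_hz", 50.0))
    sigma = float(p.pop("sigma_ms", 2.5))
    per_cycle = int(p.pop("events_per_cycle", 10))
    if p:
        raise ValueError(f"unknown burst_train parameters {sorted(p)}")
    if f <= 0 or sigma < 0 or per_cycle <= 0:
        raise ValueError("need f > 0, sigma >= 0, events_per_cycle > 0")
    rng = np.random.default_rng(spec.seed)
    means = np.arange(spec.t_start_ms, spec.t_start_ms + spec.duration_ms,
                      1000.0 / f)
    if sigma == 0:
        events = np.repeat(means, per_cycle)
    else:
        events = (means[:, None]
                  + rng.normal(0, sigma, (means.size, per_cycle))).ravel()
    lo, hi = spec.t_start_ms, spec.t_start_ms + spec.duration_ms
    events = np.sort(events[(events >= lo) & (events < hi)])
    return events, {"f_hz": f, "sigma_ms": sigma, "cycle_means": means.tolist(),
                    "events_per_cycle": per_cycle}


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the signal or event train described by ``spec``.

    Series kinds return a uniformly sampled (t, x) pair with optional
    additive Gaussian noise; event kinds return sorted event times in ``x``
    and an empty time grid.  Ground truth is exact by construction.
    """
    if spec.kind in EVENT_KINDS:
        maker = {"poisson_train": _make_poisson_train,
                 "burst_train": _make_burst_train}[spec.kind]
        events, truth = maker(spec)
        return Fixture(spec=spec, t=np.empty(0), x=events, truth=truth)
    t = _grid(spec)
    maker = {"sinusoid": _make_sinusoid, "tone_mixture": _make_tone_mixture,
             "asym_triangle": _make_asym_triangle,
             "gated_transient": _make_gated_transient}[spec.kind]
    x, truth = maker(spec, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise_sd, x.shape)
    return Fixture(spec=spec, t=t, x=x, truth=truth)
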