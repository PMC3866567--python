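"""Config-driven scenario runner.

A :class:`Scenario` bundles everything needed to reproduce one simulated
regime end-to-end: the network configuration (regime-table rows or explicit
per-layer parameters), a list of drive specifications, the simulation
duration/step, the analysis window and the master seed.  Scenarios
round-trip through YAML; a library of shipped scenario files covering every
studied regime lives in ``gammacd/data/scenarios/``.

``run_scenario`` produces a :class:`RunBundle` with spikes, per-layer
current dipole, spectral estimates and summary statistics; ``sweep`` reruns
a scenario along one addressable parameter and tabulates the results.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import analysis as _an
from . import drives as _drives
from . import network as _nw

#: analysis window shared by all scenarios (ms)
DEFAULT_WINDOW = (50.0, 550.0)

_TOP_KEYS = {"name", "layers", "network", "drives", "duration_ms", "dt_ms",
             "window_ms", "seed"}
_NETWORK_KEYS = {"regimes", "layers"}
_LAYER_KEYS = {"g_ei", "g_ie", "g_ii", "n_pyr", "n_inh",
               "weight_space_constant", "lam_ie", "lam_ii", "regime"}
_DRIVE_KEYS = {
    "tonic": {"type", "i_app", "layer", "target"},
    "poisson": {"type", "rate_hz", "g_max_uS", "layer", "target", "seed"},
    "burst": {"type", "input_class", "f_hz", "sigma_ms", "events_per_cycle",
              "per_event_conductance_pS", "distal_lag_ms", "layer", "seed"},
}


@dataclass
class Scenario:
    """One fully specified simulation regime."""

    name: str
    layers: list[str]
    network: dict                      # {"regimes": [...]} and/or {"layers": {...}}
    drives: list[dict] = field(default_factory=list)
    duration_ms: float = 550.0
    dt_ms: float = 0.025
    window_ms: tuple[float, float] = DEFAULT_WINDOW
    seed: int = 0

    # -- construction / serialization --------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "layers": list(self.layers),
            "network": copy.deepcopy(self.network),
            "drives": copy.deepcopy(self.drives),
            "duration_ms": self.duration_ms,
            "dt_ms": self.dt_ms,
            "window_ms": list(self.window_ms),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown scenario keys {sorted(unknown)}")
        missing = {"name", "layers", "network"} - set(d)
        if missing:
            raise ValueError(f"missing required scenario fields "
                             f"{sorted(missing)}")
        window = tuple(d.get("window_ms", DEFAULT_WINDOW))
        return cls(name=str(d["name"]), layers=list(d["layers"]),
                   network=copy.deepcopy(d["network"]),
                   drives=copy.deepcopy(d.get("drives", [])),
                   duration_ms=float(d.get("duration_ms", 550.0)),
                   dt_ms=float(d.get("dt_ms", 0.025)),
                   window_ms=(float(window[0]), float(window[1])),
                   seed=int(d.get("seed", 0)))

    def network_config(self) -> _nw.NetworkConfig:
        """Materialize the NetworkConfig from regime rows and/or overrides."""
        net = self.network
        cfg = _nw.NetworkConfig()
        for regime in net.get("regimes", []):
            lc = _nw.layer_config(regime)
            if lc.layer in cfg.layers:
                raise ValueError(f"duplicate configuration for layer {lc.layer}")
            cfg.layers[lc.layer] = lc
        for layer, spec in net.get("layers", {}).items():
            base = cfg.layers.get(layer)
            kw = {k: spec[k] for k in spec}
            if base is not None:
                merged = {**base.__dict__, **kw}
                merged.pop("layer", None)
                cfg.layers[layer] = _nw.LayerConfig(layer=layer, **merged)
            else:
                cfg.layers[layer] = _nw.LayerConfig(layer=layer, **kw)
        return cfg

    def drive_objects(self) -> list:
        """Instantiate drive dataclasses, deriving per-drive seeds.

        Stochastic drives without an explicit seed receive one derived from
        the scenario seed via ``numpy.random.SeedSequence`` (always below
        2**31).
        """
        ss = np.random.SeedSequence(self.seed).spawn(max(1, len(self.drives)))
        out = []
        for i, spec in enumerate(self.drives):
            kind = spec.get("type")
            derived = int(ss[i].generate_state(1)[0] % (2 ** 31))
            seed = int(spec.get("seed", derived))
            if kind == "tonic":
                out.append(_drives.TonicDrive(
                    i_app=float(spec["i_app"]), layer=spec.get("layer"),
                    target=spec.get("target", "soma")))
            elif kind == "poisson":
                out.append(_drives.PoissonDrive(
                    rate_hz=float(spec["rate_hz"]),
                    g_max=float(spec["g_max_uS"]), seed=seed,
                    layer=spec.get("layer"),
                    target=spec.get("target", "proximal")))
            elif kind == "burst":
                out.append(_drives.RhythmicBurstDrive(
                    input_class=str(spec["input_class"]),
                    f=float(spec["f_hz"]), sigma=float(spec["sigma_ms"]),
                    events_per_cycle=int(spec.get("events_per_cycle", 10)),
                    per_event_conductance_pS=float(
                        spec.get("per_event_conductance_pS", 40.0)),
                    distal_lag=float(spec.get("distal_lag_ms", 5.0)),
                    seed=seed, layer=spec.get("layer", "L5")))
            else:
                raise ValueError(f"unknown drive type {kind!r}")
        return out


# ---------------------------------------------------------------------------
# config I/O and validation
# ---------------------------------------------------------------------------

def load_config(path) -> Scenario:
    """Load and structurally validate a scenario YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: scenario file must contain a mapping")
    scenario = Scenario.from_dict(data)
    problems = validate_config(scenario)
    if problems:
        raise ValueError(f"{path}: invalid scenario:\n  " +
                         "\n  ".join(problems))
    return scenario


def write_config(scenario: Scenario, path):
    """Write a scenario as YAML (round-trip stable with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def shipped_scenarios() -> dict[str, Path]:
    """Mapping of shipped scenario names to their YAML paths."""
    base = resources.files("gammacd") / "data" / "scenarios"
    out = {}
    for entry in sorted(base.iterdir()):
        if entry.name.endswith(".yaml"):
            out[entry.name[:-5]] = Path(str(entry))
    return out


def load_shipped(name: str) -> Scenario:
    """Load one shipped scenario by name."""
    table = shipped_scenarios()
    if name not in table:
        raise ValueError(f"unknown shipped scenario {name!r}; "
                         f"options: {sorted(table)}")
    return load_config(table[name])


def validate_config(scenario: Scenario) -> list[str]:
    """Return a list of problems (empty when the scenario is valid)."""
    problems: list[str] = []
    if not scenario.name:
        problems.append("name: must be nonempty")
    for layer in scenario.layers:
        if layer not in _nw.LAYERS:
            problems.append(f"layers: unknown layer {layer!r}")
    unknown = set(scenario.network) - _NETWORK_KEYS
    if unknown:
        problems.append(f"network: unknown keys {sorted(unknown)}")
    for regime in scenario.network.get("regimes", []):
        if regime not in _nw.TABLE1:
            problems.append(f"network.regimes: unknown regime {regime!r}")
    for layer, spec in scenario.network.get("layers", {}).items():
        bad = set(spec) - _LAYER_KEYS
        if bad:
            problems.append(f"network.layers.{layer}: unknown keys {sorted(bad)}")
        for g in ("g_ei", "g_ie", "g_ii"):
            if g in spec and spec[g] < 0:
                problems.append(f"network.layers.{layer}.{g}: must be >= 0")
    try:
        cfg = scenario.network_config()
        cfg.validate()
        for layer in scenario.layers:
            if layer not in cfg.layers:
                problems.append(f"layers: no network configuration for {layer!r}")
    except (ValueError, TypeError) as exc:
        problems.append(f"network: {exc}")
    for i, spec in enumerate(scenario.drives):
        kind = spec.get("type")
        if kind not in _DRIVE_KEYS:
            problems.append(f"drives[{i}].type: unknown type {kind!r}")
            continue
        bad = set(spec) - _DRIVE_KEYS[kind]
        if bad:
            problems.append(f"drives[{i}]: unknown keys {sorted(bad)}")
        for key, cond, msg in (
                ("rate_hz", lambda v: v >= 0, ">= 0"),
                ("g_max_uS", lambda v: v >= 0, ">= 0"),
                ("f_hz", lambda v: v > 0, "> 0"),
                ("sigma_ms", lambda v: v >= 0, ">= 0")):
            if key in spec and not cond(spec[key]):
                problems.append(f"drives[{i}].{key}: must be {msg}")
    if scenario.duration_ms <= 0 or scenario.dt_ms <= 0:
        problems.append("duration_ms and dt_ms must be positive")
    lo, hi = scenario.window_ms
    if not (0 <= lo < hi <= scenario.duration_ms):
        problems.append("window_ms must satisfy 0 <= start < stop <= duration")
    return problems


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

@dataclass
class RunBundle:
    """Everything produced by one scenario run."""

    scenario: Scenario
    config: dict                      # config snapshot
    config_hash: str
    seed: int
    wall_time_s: float
    t: np.ndarray                     # analysis-window time grid (ms)
    dipole: dict[str, np.ndarray]     # per-layer CD over the window (nAm)
    spike_time: np.ndarray
    spike_cell: np.ndarray
    stats: dict                       # per-layer summary statistics
    periodograms: dict[str, _an.Periodogram]
    spectrograms: dict[str, _an.Spectrogram]
    result: object = None             # full RunResult


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _layer_stats(t, q, result, layer, window) -> dict:
    lo, hi = window
    e_rates = [np.sum((s > lo) & (s <= hi)) / ((hi - lo) / 1000.0)
               for s in result.spike_times_of("E", layer)]
    i_rates = [np.sum((s > lo) & (s <= hi)) / ((hi - lo) / 1000.0)
               for s in result.spike_times_of("I", layer)]
    stats = {
        "max_abs_cd_nAm": float(np.max(np.abs(q))),
        "e_rate_mean_hz": float(np.mean(e_rates)),
        "e_rate_sd_hz": float(np.std(e_rates)),
        "i_rate_mean_hz": float(np.mean(i_rates)),
        "n_spikes": int(sum(np.sum((s > lo) & (s <= hi))
                            for s in (result.spike_time,))),
    }
    try:
        f_pk, p_pk = _an.welch_periodogram(t, q).peak(20.0, 150.0)
        stats["welch_peak_f_hz"] = float(f_pk)
        stats["welch_peak_power"] = float(p_pk)
    except ValueError:
        pass
    sp = _an.morlet_spectrogram(t, q)
    _, f_m, p_m = sp.band(30.0, 100.0).peak
    stats["morlet_peak_f_hz"] = float(f_m)
    stats["morlet_peak_power"] = float(p_m)
    sr = _an.slope_ratio_of_series(t, q)
    stats["phi"] = sr.phi
    stats["phi_se"] = sr.se
    stats["n_cycles"] = sr.n_cycles
    if sr.n_cycles >= 3:
        stats["phi_p_value"] = sr.p_value()
    epochs = _an.find_high_gamma_epochs(sp)
    stats["high_gamma_epochs"] = [
        {"t_max_ms": e.t_max, "f_hz": e.f, "power": e.power,
         "window_ms": list(e.window)} for e in epochs]
    return stats


def run_scenario(scenario: Scenario, params: dict | None = None) -> RunBundle:
    """Run one scenario end-to-end and compute its summary statistics.

    Deterministic given the scenario (including its seed): identical
    configurations produce bit-identical bundles.
    """
    problems = validate_config(scenario)
    if problems:
        raise ValueError("invalid scenario:\n  " + "\n  ".join(problems))
    t0 = time.perf_counter()
    cfg = scenario.network_config()
    net = _nw.build_network(set(scenario.layers), cfg, params=params)
    _drives.attach_drives(net, scenario.drive_objects(), scenario.duration_ms)
    result = net.run(scenario.duration_ms, scenario.dt_ms)
    lo, hi = scenario.window_ms
    m = (result.t >= lo) & (result.t <= hi)
    t = result.t[m]
    dipole = {layer: result.dipole.layers[layer][m]
              for layer in scenario.layers}
    stats, pgs, sgs = {}, {}, {}
    for layer in scenario.layers:
        q = dipole[layer]
        stats[layer] = _layer_stats(t, q, result, layer, scenario.window_ms)
        pgs[layer] = _an.welch_periodogram(t, q)
        sgs[layer] = _an.morlet_spectrogram(t, q)
    snapshot = scenario.to_dict()
    return RunBundle(
        scenario=scenario, config=snapshot, config_hash=config_hash(snapshot),
        seed=scenario.seed, wall_time_s=time.perf_counter() - t0,
        t=t, dipole=dipole, spike_time=result.spike_time,
        spike_cell=result.spike_cell, stats=stats,
        periodograms=pgs, spectrograms=sgs, result=result)


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

def _resolve_drive(scenario: Scenario, selector: str) -> int:
    """Drive index from a selector: integer position, drive type, or the
    input class of a burst drive."""
    if selector.isdigit():
        i = int(selector)
        if i >= len(scenario.drives):
            raise ValueError(f"drive index {i} out of range")
        return i
    for i, spec in enumerate(scenario.drives):
        if spec.get("type") == selector or spec.get("input_class") == selector:
            return i
    raise ValueError(f"no drive matches selector {selector!r}")


def set_parameter(scenario: Scenario, parameter: str, value) -> Scenario:
    """Return a copy of the scenario with one addressable parameter changed.

    Addresses: ``seed``, ``duration_ms``, ``drives.<selector>.<field>`` where
    the selector is a position, a drive type, or a burst input class (e.g.
    ``drives.proximal.sigma_ms``), and ``network.<layer>.<field>``.
    """
    s = Scenario.from_dict(scenario.to_dict())
    parts = parameter.split(".")
    if parts == ["seed"]:
        s.seed = int(value)
    elif parts == ["duration_ms"]:
        s.duration_ms = float(value)
    elif len(parts) == 3 and parts[0] == "drives":
        i = _resolve_drive(s, parts[1])
        field_name = parts[2]
        allowed = _DRIVE_KEYS[s.drives[i]["type"]]
        if field_name not in allowed:
            raise ValueError(f"drive field {field_name!r} not addressable "
                             f"for type {s.drives[i]['type']!r}")
        s.drives[i][field_name] = value
    elif len(parts) == 3 and parts[0] == "network":
        layer, field_name = parts[1], parts[2]
        if field_name not in _LAYER_KEYS:
            raise ValueError(f"unknown network field {field_name!r}")
        s.network.setdefault("layers", {}).setdefault(layer, {})[
            field_name] = value
    else:
        raise ValueError(f"parameter {parameter!r} is not addressable")
    return s


def sweep(parameter: str, values, scenario: Scenario,
          params: dict | None = None):
    """Run the scenario once per parameter value and tabulate the results.

    Returns a pandas DataFrame with one row per value: Welch peak frequency
    and power, Phi with its standard error, and the power change relative
    to the first value.  Statistics refer to the scenario's first layer.
    """
    import pandas as pd

    values = list(values)
    if not values:
        raise ValueError("sweep needs at least one value")
    layer = scenario.layers[0]
    rows = []
    for v in values:
        bundle = run_scenario(set_parameter(scenario, parameter, v), params)
        st = bundle.stats[layer]
        rows.append({
            "value": v,
            "peak_f_hz": st.get("welch_peak_f_hz", float("nan")),
            "max_PW": st.get("welch_peak_power", float("nan")),
            "phi": st["phi"],
            "phi_se": st["phi_se"],
            "max_abs_cd_nAm": st["max_abs_cd_nAm"],
        })
    df = pd.DataFrame(rows)
    df["rel_PW"] = df["max_PW"] / df["max_PW"].iloc[0]
    return df
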