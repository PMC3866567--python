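"""Cell models: reduced-morphology pyramidal cells and fast-spiking baskets.

Three cell classes are supported:

``l23_pyramidal``
    Eight coupled compartments (soma, apical trunk / middle / tuft, one
    oblique dendrite parallel to the laminae, and three basilar
    compartments) carrying Na, K, Kdr, Km and leak currents.
``l5_pyramidal``
    Same layout plus one additional apical compartment (total apical-axis
    extent exactly 2.21x the L2/3 cell) and additional Ca, CaT, h and KCa
    currents with an intracellular calcium pool.
``basket``
    A single-compartment fast-spiking inhibitory cell with Na, K and leak.

Geometry and maximal conductances are read from the versioned parameter
file ``data/cell_parameters.yaml``.  Compartments longer than 100 um are
discretized with one extra internal point; the resulting *segments* are the
nodes of the cable system and carry the signed apical-axis projections
``z_i`` and axial resistances ``r_i`` used by the current-dipole forward
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

CELL_KINDS = ("l23_pyramidal", "l5_pyramidal", "basket")

#: channel slots understood by the integration engine
CHANNEL_NAMES = ("na", "k", "kdr", "km", "ca", "cat", "h", "kca", "leak")

_REQUIRED_CHANNELS = {
    "l23_pyramidal": {"na", "k", "kdr", "km", "leak"},
    "l5_pyramidal": {"na", "k", "kdr", "km", "ca", "cat", "h", "kca", "leak"},
    "basket": {"na", "k", "leak"},
}


def load_parameters() -> dict:
    """Load the versioned cell/synapse parameter file shipped with the package."""
    ref = resources.files("gammacd").joinpath("data/cell_parameters.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class CompartmentGeometry:
    """One cylindrical compartment of a reduced cell morphology.

    ``z_projection`` is the signed length component along the apical axis
    (positive toward the pia); it is zero for the oblique dendrite, which is
    excluded from the current-dipole calculation by construction.
    """

    name: str
    parent: str | None
    length: float            # um
    diameter: float          # um
    z_projection: float      # um, signed, |z| <= length
    axial_resistivity: float  # ohm cm (cell-level constant, repeated here)

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"compartment {self.name!r}: nonpositive dimensions")
        if abs(self.z_projection) > self.length + 1e-9:
            raise ValueError(
                f"compartment {self.name!r}: |z_projection| exceeds length"
            )

    @property
    def n_internal_points(self) -> int:
        """Compartments longer than 100 um carry one extra internal point."""
        return 2 if self.length > 100.0 else 1

    @property
    def area_cm2(self) -> float:
        """Lateral cylinder area in cm^2."""
        return math.pi * self.diameter * self.length * 1e-8

    @property
    def axial_resistance_Mohm(self) -> float:
        """End-to-end axial resistance of the full compartment in Mohm."""
        r_cm = self.diameter / 2.0 * 1e-4
        l_cm = self.length * 1e-4
        return self.axial_resistivity * l_cm / (math.pi * r_cm**2) / 1e6

    @property
    def axial_resistance_to_parent(self) -> float:
        """Half the compartment's own axial resistance (Mohm); the coupling
        resistance to the parent adds the parent's half."""
        return self.axial_resistance_Mohm / 2.0


@dataclass(frozen=True)
class ChannelSet:
    """Per-compartment maximal conductance densities (mS/cm^2) and reversals (mV)."""

    gbar: dict[str, float]          # channel -> density, mS/cm^2
    reversal: dict[str, float]      # channel family -> reversal, mV
    leak_reversal: float

    def __post_init__(self):
        for name, g in self.gbar.items():
            if name not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel {name!r}")
            if g < 0:
                raise ValueError(f"channel {name!r}: negative maximal conductance")


@dataclass(frozen=True)
class Segment:
    """One discretization node of the cable system."""

    index: int
    compartment: str
    parent_index: int        # -1 for the root
    length: float            # um
    diameter: float          # um
    z_projection: float      # um, signed
    area_cm2: float
    g_axial_uS: float        # coupling conductance to parent segment (0 at root)


@dataclass
class CellModel:
    """Geometry + channels for one neuron, ready for network assembly."""

    kind: str
    compartments: list[CompartmentGeometry]
    channels: ChannelSet
    cm: float                # uF/cm^2
    axial_resistivity: float  # ohm cm
    comp_channel_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def comp_index(self) -> dict[str, int]:
        return {c.name: i for i, c in enumerate(self.compartments)}

    def apical_axis_extent(self) -> float:
        """Summed length of the apical compartments (um)."""
        return sum(c.length for c in self.compartments if c.name.startswith("apical")
                   and c.name != "apical_oblique")

    def segments(self) -> list[Segment]:
        """Flatten compartments into cable segments (parent-before-child order).

        Compartments with an extra internal point are split into two equal
        segments; the signed z projection is divided equally.  Coupling
        conductances are computed between segment centres (half-resistance of
        each side, in Mohm -> uS).
        """
        segs: list[Segment] = []
        last_seg_of_comp: dict[str, int] = {}
        half_r: list[float] = []  # Mohm, half axial resistance of each segment

        for comp in self.compartments:
            n = comp.n_internal_points
            l_seg = comp.length / n
            r_seg = (self.axial_resistivity * (l_seg * 1e-4)
                     / (math.pi * (comp.diameter / 2.0 * 1e-4) ** 2) / 1e6)
            for j in range(n):
                idx = len(segs)
                if j == 0:
                    parent = -1 if comp.parent is None else last_seg_of_comp[comp.parent]
                else:
                    parent = idx - 1
                if parent < 0:
                    g_ax = 0.0
                else:
                    g_ax = 1.0 / (r_seg / 2.0 + half_r[parent])
                segs.append(Segment(
                    index=idx,
                    compartment=comp.name,
                    parent_index=parent,
                    length=l_seg,
                    diameter=comp.diameter,
                    z_projection=comp.z_projection / n,
                    area_cm2=comp.area_cm2 / n,
                    g_axial_uS=g_ax,
                ))
                half_r.append(r_seg / 2.0)
                last_seg_of_comp[comp.name] = idx
        return segs

    def segment_gbar(self, channel: str) -> np.ndarray:
        """Absolute conductance (uS) of ``channel`` for every segment."""
        out = []
        for seg in self.segments():
            dens = self.comp_channel_overrides.get(seg.compartment, {}).get(
                channel, self.channels.gbar.get(channel, 0.0))
            out.append(dens * seg.area_cm2 * 1e3)  # mS/cm^2 * cm^2 -> mS -> uS
        return np.asarray(out)


def build_cell(kind: str, params: dict | None = None) -> CellModel:
    """Construct one of the three cell models from the parameter file.

    Raises ``ValueError`` for an unknown ``kind``.
    """
    if kind not in CELL_KINDS:
        raise ValueError(
            f"unknown cell kind {kind!r}; expected one of {CELL_KINDS}")
    params = params if params is not None else load_parameters()
    spec = params["cells"][kind]
    ra = float(spec["axial_resistivity_ohm_cm"])
    comps = [
        CompartmentGeometry(
            name=c["name"],
            parent=c["parent"],
            length=float(c["length_um"]),
            diameter=float(c["diameter_um"]),
            z_projection=float(c["z_projection_um"]),
            axial_resistivity=ra,
        )
        for c in spec["compartments"]
    ]
    gbar = {name: float(ch["gbar_mS_cm2"]) for name, ch in spec["channels"].items()}
    missing = _REQUIRED_CHANNELS[kind] - set(gbar)
    if missing:
        raise ValueError(f"{kind}: parameter file missing channels {sorted(missing)}")
    channels = ChannelSet(
        gbar=gbar,
        reversal={k: float(v) for k, v in params["reversal_potentials_mV"].items()},
        leak_reversal=float(spec["channels"]["leak"].get("reversal_mV", -65.0)),
    )
    overrides = {
        name: {ch: float(g) for ch, g in chans.items()}
        for name, chans in spec.get("channel_overrides", {}).items()
    }
    return CellModel(
        kind=kind,
        compartments=comps,
        channels=channels,
        cm=float(spec["cm_uF_cm2"]),
        axial_resistivity=ra,
        comp_channel_overrides=overrides,
    )


def integrate_cell(model: CellModel, inputs: dict | None = None,
                   dt: float = 0.025, duration: float = 550.0,
                   v_init: float | None = None,
                   params: dict | None = None) -> dict:
    """Integrate a single isolated cell and return its voltage trajectory.

    ``inputs`` may contain:

    ``current``
        mapping compartment name -> injected somatic-style current, either a
        scalar (nA, constant) or an array of nA values on the time grid;
    ``ampa_events`` / ``gaba_events``
        mapping compartment name -> (event_times_ms, conductance_uS) tuples.

    Returns a dict with ``t`` (ms), ``v`` (n_times, n_segments, mV),
    ``segments`` (the segment table) and ``dipole`` (nAm, apical-axis CD of
    this one cell).  Raises ``engine.NumericalInstability`` with the
    offending compartment and time if the voltage diverges.
    """
    from . import engine as _engine

    params = params if params is not None else load_parameters()
    inputs = inputs or {}
    n_steps = int(round(duration / dt))
    segs = model.segments()
    n_seg = len(segs)
    comp_first = {}
    for s in segs:
        comp_first.setdefault(s.compartment, s.index)

    parent = np.asarray([s.parent_index for s in segs], np.int64)
    g_ax = np.asarray([s.g_axial_uS for s in segs])
    child_sum = np.zeros(n_seg)
    for s in range(n_seg):
        if parent[s] >= 0:
            child_sum[parent[s]] += g_ax[s]
    area = np.asarray([s.area_cm2 for s in segs])
    z = np.asarray([s.z_projection for s in segs])

    i_tonic = np.zeros(n_seg)
    inj_seg, inj_traces = [], []
    for comp, cur in inputs.get("current", {}).items():
        if comp not in comp_first:
            raise ValueError(f"unknown compartment {comp!r}")
        if np.isscalar(cur):
            i_tonic[comp_first[comp]] += float(cur)
        else:
            cur = np.asarray(cur, float)
            if cur.shape[0] < n_steps:
                raise ValueError("current trace must cover the full duration")
            inj_seg.append(comp_first[comp])
            inj_traces.append(cur[:n_steps])
    ev_time, ev_seg, ev_w, ev_rec = [], [], [], []
    for key, rec in (("ampa_events", _engine.AMPA), ("gaba_events", _engine.GABA_A)):
        for comp, (times, w) in inputs.get(key, {}).items():
            for ts in np.atleast_1d(times):
                ev_time.append(float(ts)); ev_seg.append(comp_first[comp])
                ev_w.append(float(w)); ev_rec.append(rec)

    syn = params["synapses"]
    rev = params["reversal_potentials_mV"]
    ca = params["calcium"]
    gbars = {ch: model.segment_gbar(ch) for ch in CHANNEL_NAMES}
    assembled = {
        "parent": parent, "g_ax": g_ax, "child_gax_sum": child_sum,
        "c_nF": model.cm * area * 1e3, "area": area, "z_um": z,
        "e_leak": np.full(n_seg, model.channels.leak_reversal),
        **{f"g_{ch}": gbars[ch] for ch in CHANNEL_NAMES},
        "e_na": float(rev["na"]), "e_k": float(rev["k"]),
        "e_ca": float(rev["ca"]), "e_h": float(rev["h"]),
        "ca_tau": float(ca["tau_ms"]), "ca_rest": float(ca["rest_mM"]),
        "ca_drive_factor": 1e4 / (2 * 96485.0 * float(ca["depth_um"])),
        "syn_tau": np.array([
            [syn["ampa"]["rise_tau_ms"], syn["ampa"]["decay_tau_ms"]],
            [syn["gaba_a"]["rise_tau_ms"], syn["gaba_a"]["decay_tau_ms"]]]),
        "e_syn": np.array([syn["ampa"]["reversal_mV"],
                           syn["gaba_a"]["reversal_mV"]]),
        "delay_ms": float(syn["delivery_delay_ms"]),
        "soma_idx": np.asarray([comp_first["soma"]], np.int64),
        "conn_ptr": np.zeros(2, np.int64),
        "conn_seg": np.empty(0, np.int64), "conn_w": np.empty(0),
        "conn_rec": np.empty(0, np.int64),
        "ev_time": np.asarray(ev_time), "ev_seg": np.asarray(ev_seg, np.int64),
        "ev_w": np.asarray(ev_w), "ev_rec": np.asarray(ev_rec, np.int64),
        "i_tonic": i_tonic,
        "inj_seg": np.asarray(inj_seg, np.int64),
        "inj_traces": (np.column_stack(inj_traces) if inj_traces
                       else np.empty((0, 0))),
        "dip_seg": np.flatnonzero((parent >= 0) & (z != 0)).astype(np.int64),
        "dip_layer": np.zeros(np.count_nonzero((parent >= 0) & (z != 0)), np.int64),
        "n_layers": 1,
        "gaba_seg": np.empty(0, np.int64), "gaba_layer": np.empty(0, np.int64),
        "rec_idx": np.arange(n_seg, dtype=np.int64),
        "v_init": float(params["v_rest_init_mV"] if v_init is None else v_init),
        "spike_threshold": float(params["spike_threshold_mV"]),
    }
    out = _engine.run(assembled, duration, dt)
    return {"t": out["t"], "v": out["v_rec"], "segments": segs,
            "dipole": out["dipole"][:, 0],
            "spike_times": out["spike_time"]}


def detect_spikes(time_ms: np.ndarray, voltage_mV: np.ndarray,
                  threshold: float = 0.0, refractory_ms: float = 1.0) -> np.ndarray:
    """Times of upward threshold crossings, coalescing crossings closer than
    ``refractory_ms``.

    Returns a strictly increasing array of spike times (ms); empty if the
    trace never crosses threshold.
    """
    v = np.asarray(voltage_mV, float)
    t = np.asarray(time_ms, float)
    if v.shape != t.shape:
        raise ValueError("time and voltage must have the same shape")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    if up.size == 0:
        return np.empty(0)
    times = t[up]
    keep = [times[0]]
    for ts in times[1:]:
        if ts - keep[-1] >= refractory_ms:
            keep.append(ts)
    return np.asarray(keep)
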