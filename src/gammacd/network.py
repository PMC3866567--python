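"""Two-layer network construction: populations, synapses, distance-scaled weights.

Each simulated layer ("L2/3", "L5") holds 100 multi-compartment pyramidal
cells on a 10x10 grid and 35 single-compartment fast-spiking basket cells
interleaved on the same grid extent.  Within a layer, connectivity is
effectively all-to-all with Gaussian distance scaling:

* E -> I: AMPA onto the basket compartment (``g_ei``),
* I -> E: GABA_A onto the pyramidal soma (``g_ie``),
* I -> I: GABA_A onto the basket compartment (``g_ii``; zero in the
  strong-PING regime).

E -> E and interlaminar synapses are structurally excluded.  Synaptic
maximal conductances (``g_ei``, ``g_ie``, ``g_ii``) are absolute
conductances in uS per connection before distance scaling, the weight
convention of this model lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import cells as _cells
from . import engine as _engine

LAYERS = ("L2/3", "L5")
_PYR_KIND = {"L2/3": "l23_pyramidal", "L5": "l5_pyramidal"}


@dataclass(frozen=True)
class SynapseSpec:
    """Kinetics and placement of one synapse class."""

    transmitter: str            # "AMPA" | "GABA_A"
    rise_tau: float             # ms
    decay_tau: float            # ms
    reversal: float             # mV
    g_max: float                # uS per connection
    delivery_delay: float = 1.0  # ms
    target_compartment: str = "soma"

    def __post_init__(self):
        if self.transmitter not in ("AMPA", "GABA_A"):
            raise ValueError(f"unknown transmitter {self.transmitter!r}")
        if not self.decay_tau > self.rise_tau > 0:
            raise ValueError("need decay_tau > rise_tau > 0")
        if self.g_max < 0:
            raise ValueError("g_max must be nonnegative")


@dataclass
class LayerConfig:
    """Population sizes and synaptic strengths for one layer (regime table row)."""

    layer: str
    g_ei: float                  # uS, AMPA E->I
    g_ie: float                  # uS, GABA_A I->E
    g_ii: float                  # uS, GABA_A I->I (0 in strong PING)
    n_pyr: int = 100
    n_inh: int = 35
    weight_space_constant: float = 3.0   # grid units, E->I (default for all)
    #: Per-connection-class space constants (grid units).  The model lineage
    #: uses a short constant for pyramidal->basket excitation and much broader
    #: constants for basket output, keeping somatic inhibition broadly shared
    #: across the 10x10 grid; None falls back to weight_space_constant.
    lam_ie: float | None = 30.0
    lam_ii: float | None = 20.0
    regime: str = ""

    @property
    def lam_ei_eff(self) -> float:
        return self.weight_space_constant

    @property
    def lam_ie_eff(self) -> float:
        return self.weight_space_constant if self.lam_ie is None else self.lam_ie

    @property
    def lam_ii_eff(self) -> float:
        return self.weight_space_constant if self.lam_ii is None else self.lam_ii

    def validate(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        for name in ("g_ei", "g_ie", "g_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.weight_space_constant <= 0:
            raise ValueError("weight_space_constant must be positive")
        if self.lam_ie_eff <= 0 or self.lam_ii_eff <= 0:
            raise ValueError("space constants must be positive")
        if self.n_pyr < 1 or self.n_inh < 0:
            raise ValueError("population counts out of range")


#: Regime parameter table (conductances uS per connection; drives listed for reference
#: and realized by gammacd.drives).
TABLE1 = {
    "l5_strong_ping": dict(layer="L5", g_ei=6e-5, g_ie=3e-1, g_ii=0.0,
                           regime="strong_ping", i_app=6.0),
    "l5_weak_ping": dict(layer="L5", g_ei=9.1e-4, g_ie=8e-2, g_ii=7.5e-3,
                         regime="weak_ping", lambda_pois=40.0, g_pois=1e-2),
    # figure variant of the L5 weak-PING row with reduced Poisson conductance
    "l5_weak_ping_fig": dict(layer="L5", g_ei=9.1e-4, g_ie=8e-2, g_ii=7.5e-3,
                             regime="weak_ping", lambda_pois=40.0, g_pois=0.75e-2),
    "l2_weak_ping": dict(layer="L2/3", g_ei=1.2e-3, g_ie=7e-3, g_ii=1e-2,
                         regime="weak_ping", lambda_pois=140.0, g_pois=0.8e-3),
}


def layer_config(regime: str) -> LayerConfig:
    """A LayerConfig for one named regime-table row."""
    if regime not in TABLE1:
        raise ValueError(f"unknown regime {regime!r}; options: {sorted(TABLE1)}")
    row = {k: v for k, v in TABLE1[regime].items()
           if k in ("layer", "g_ei", "g_ie", "g_ii", "regime")}
    cfg = LayerConfig(**row)
    cfg.validate()
    return cfg


@dataclass
class NetworkConfig:
    """Per-layer configuration of the laminar network."""

    layers: dict[str, LayerConfig] = field(default_factory=dict)

    @classmethod
    def from_regimes(cls, *regimes: str) -> "NetworkConfig":
        cfg = cls()
        for r in regimes:
            lc = layer_config(r)
            if lc.layer in cfg.layers:
                raise ValueError(f"duplicate configuration for layer {lc.layer}")
            cfg.layers[lc.layer] = lc
        return cfg

    def validate(self):
        for name, lc in self.layers.items():
            if name != lc.layer:
                raise ValueError("layer key/value mismatch")
            lc.validate()


def weight_scale(distance, space_constant: float):
    """Gaussian distance scaling exp(-(d/lambda)^2), 1 at d = 0."""
    if space_constant <= 0:
        raise ValueError("space constant must be positive")
    d = np.asarray(distance, float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = np.exp(-((d / space_constant) ** 2))
    return float(out) if out.ndim == 0 else out


def _pyr_grid(n: int) -> np.ndarray:
    side = math.ceil(math.sqrt(n))
    xs, ys = np.meshgrid(np.arange(side, dtype=float),
                         np.arange(side, dtype=float))
    return np.column_stack([xs.ravel(), ys.ravel()])[:n]


def _inh_grid(n: int, extent: float) -> np.ndarray:
    # interleave the basket cells on a coarser lattice spanning the same extent
    ncols = max(2, math.ceil(math.sqrt(n)))
    nrows = math.ceil(n / ncols)
    xs = np.linspace(0.25, extent - 0.25, ncols)
    ys = np.linspace(0.25, extent - 0.25, nrows)
    pos = [(x, y) for y in ys for x in xs]
    return np.asarray(pos[:n], float)


@dataclass
class CellRef:
    """Bookkeeping for one cell inside an assembled network."""

    index: int                # global cell index
    kind: str
    role: str                 # "E" | "I"
    layer: str
    pop_index: int            # index within its population
    position: np.ndarray      # grid units, shape (2,)
    seg_offset: int
    n_seg: int
    soma_seg: int
    comp_segs: dict[str, list[int]]


def _fast_ampa_tau(syn: dict) -> np.ndarray | None:
    """(rise, decay) of AMPA onto interneurons, if configured separately."""
    fast = syn.get("ampa_on_inh")
    if fast is None:
        return None
    return np.array([float(fast["rise_tau_ms"]), float(fast["decay_tau_ms"])])


class Network:
    """Assembled laminar network: cells, cable segments, and synapse lists."""

    def __init__(self, config: NetworkConfig, params: dict | None = None):
        config.validate()
        if not config.layers:
            raise ValueError("network needs at least one configured layer")
        self.config = config
        self.params = params if params is not None else _cells.load_parameters()
        self.layer_names = [l for l in LAYERS if l in config.layers]
        self.cells: list[CellRef] = []
        self.models: dict[str, _cells.CellModel] = {}
        self._seg_arrays: dict[str, list] = {
            k: [] for k in ("parent", "g_ax", "area", "c_nF", "z_um", "e_leak")}
        self._seg_gbar: dict[str, list] = {c: [] for c in _cells.CHANNEL_NAMES}
        # synapse edge list: (pre_cell, post_cell, post_seg, receptor, weight_uS)
        self.edges: list[tuple] = []
        self.i_tonic: np.ndarray | None = None
        self.events: list[tuple] = []   # (time_ms, seg, weight_uS, receptor)
        # per-segment AMPA kinetics overrides: seg -> (rise_ms, decay_ms)
        self.ampa_tau_override: dict[int, tuple[float, float]] = {}
        self._build()

    # -- construction -----------------------------------------------------
    def _model(self, kind: str) -> _cells.CellModel:
        if kind not in self.models:
            self.models[kind] = _cells.build_cell(kind, self.params)
        return self.models[kind]

    def _add_cell(self, kind: str, role: str, layer: str, pop_index: int,
                  position) -> CellRef:
        model = self._model(kind)
        segs = model.segments()
        offset = len(self._seg_arrays["parent"])
        comp_segs: dict[str, list[int]] = {}
        for seg in segs:
            self._seg_arrays["parent"].append(
                -1 if seg.parent_index < 0 else seg.parent_index + offset)
            self._seg_arrays["g_ax"].append(seg.g_axial_uS)
            self._seg_arrays["area"].append(seg.area_cm2)
            self._seg_arrays["c_nF"].append(model.cm * seg.area_cm2 * 1e3)
            self._seg_arrays["z_um"].append(seg.z_projection)
            self._seg_arrays["e_leak"].append(model.channels.leak_reversal)
            comp_segs.setdefault(seg.compartment, []).append(seg.index + offset)
        for chan in _cells.CHANNEL_NAMES:
            self._seg_gbar[chan].extend(model.segment_gbar(chan))
        ref = CellRef(
            index=len(self.cells), kind=kind, role=role, layer=layer,
            pop_index=pop_index, position=np.asarray(position, float),
            seg_offset=offset, n_seg=len(segs),
            soma_seg=comp_segs["soma"][0], comp_segs=comp_segs)
        self.cells.append(ref)
        return ref

    def _build(self):
        syn = self.params["synapses"]
        self.synapse_specs = {
            "AMPA": SynapseSpec("AMPA", syn["ampa"]["rise_tau_ms"],
                                syn["ampa"]["decay_tau_ms"],
                                syn["ampa"]["reversal_mV"], 0.0,
                                syn["delivery_delay_ms"]),
            "GABA_A": SynapseSpec("GABA_A", syn["gaba_a"]["rise_tau_ms"],
                                  syn["gaba_a"]["decay_tau_ms"],
                                  syn["gaba_a"]["reversal_mV"], 0.0,
                                  syn["delivery_delay_ms"]),
        }
        for layer in self.layer_names:
            lc = self.config.layers[layer]
            pyr_pos = _pyr_grid(lc.n_pyr)
            extent = float(pyr_pos.max()) if len(pyr_pos) else 1.0
            inh_pos = _inh_grid(lc.n_inh, max(extent, 1.0))
            e_refs = [self._add_cell(_PYR_KIND[layer], "E", layer, i, pyr_pos[i])
                      for i in range(lc.n_pyr)]
            i_refs = [self._add_cell("basket", "I", layer, i, inh_pos[i])
                      for i in range(lc.n_inh)]
            for pre in e_refs:
                for post in i_refs:
                    self.connect(pre, post, "AMPA", lc.g_ei, lc.lam_ei_eff)
            for pre in i_refs:
                for post in e_refs:
                    self.connect(pre, post, "GABA_A", lc.g_ie, lc.lam_ie_eff)
            if lc.g_ii > 0:
                for pre in i_refs:
                    for post in i_refs:
                        if pre is not post:
                            self.connect(pre, post, "GABA_A", lc.g_ii,
                                         lc.lam_ii_eff)
        n_seg = len(self._seg_arrays["parent"])
        self.i_tonic = np.zeros(n_seg)

    def connect(self, pre: CellRef, post: CellRef, transmitter: str,
                g_uS: float, space_constant: float,
                target_compartment: str = "soma"):
        """Add one distance-scaled synapse.  E->E and interlaminar pairs are
        structurally excluded from this model and are rejected."""
        if pre.role == "E" and post.role == "E":
            raise ValueError("E->E synapses are excluded from this model")
        if pre.layer != post.layer:
            raise ValueError("interlaminar synapses are excluded from this model")
        if g_uS < 0:
            raise ValueError("synaptic conductance must be nonnegative")
        if g_uS == 0:
            return
        d = float(np.linalg.norm(pre.position - post.position))
        seg = post.comp_segs[target_compartment][0]
        w = g_uS * weight_scale(d, space_constant)  # uS
        rec = _engine.AMPA if transmitter == "AMPA" else _engine.GABA_A
        self.edges.append((pre.index, post.index, seg, rec, w))

    def _inh_seg_mask(self) -> np.ndarray:
        """Boolean mask over all segments marking interneuron segments."""
        mask = np.zeros(len(self._seg_arrays["parent"]), bool)
        for c in self.cells:
            if c.role == "I":
                mask[c.seg_offset:c.seg_offset + c.n_seg] = True
        return mask

    # -- drive hooks (used by gammacd.drives) ------------------------------
    def add_tonic_current(self, cell: CellRef, compartment: str, i_nA: float):
        self.i_tonic[cell.comp_segs[compartment][0]] += i_nA

    def add_event(self, time_ms: float, seg: int, weight_uS: float, receptor: int):
        self.events.append((time_ms, seg, weight_uS, receptor))

    def set_ampa_kinetics(self, segs, rise_tau_ms: float, decay_tau_ms: float):
        """Override AMPA rise/decay time constants on specific segments."""
        if rise_tau_ms <= 0 or decay_tau_ms <= rise_tau_ms:
            raise ValueError("need 0 < rise_tau < decay_tau")
        for s in segs:
            self.ampa_tau_override[int(s)] = (float(rise_tau_ms),
                                              float(decay_tau_ms))

    # -- convenience views -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cells_of(self, role: str, layer: str | None = None) -> list[CellRef]:
        return [c for c in self.cells
                if c.role == role and (layer is None or c.layer == layer)]

    def edge_list(self):
        """Edge list as a pandas DataFrame (pre, post, transmitter, weight, delay)."""
        import pandas as pd
        delay = self.params["synapses"]["delivery_delay_ms"]
        rows = [(pre, post, "AMPA" if rec == _engine.AMPA else "GABA_A", w, delay)
                for pre, post, _seg, rec, w in self.edges]
        return pd.DataFrame(rows, columns=["pre", "post", "transmitter",
                                           "weight_uS", "delay_ms"])

    # -- engine assembly ---------------------------------------------------
    def assemble(self, record_segments=(), record_somas: bool = False) -> dict:
        sa = {k: np.asarray(v, float) for k, v in self._seg_arrays.items()}
        parent = np.asarray(self._seg_arrays["parent"], np.int64)
        n_seg = parent.shape[0]
        child_sum = np.zeros(n_seg)
        g_ax = sa["g_ax"]
        for s in range(n_seg):
            if parent[s] >= 0:
                child_sum[parent[s]] += g_ax[s]

        conn = sorted(self.edges)  # by pre index
        conn_ptr = np.zeros(self.n_cells + 1, np.int64)
        for pre, *_ in conn:
            conn_ptr[pre + 1] += 1
        conn_ptr = np.cumsum(conn_ptr)
        conn_seg = np.asarray([e[2] for e in conn], np.int64)
        conn_rec = np.asarray([e[3] for e in conn], np.int64)
        conn_w = np.asarray([e[4] for e in conn], float)

        ev = sorted(self.events)
        ev_time = np.asarray([e[0] for e in ev], float)
        ev_seg = np.asarray([e[1] for e in ev], np.int64)
        ev_w = np.asarray([e[2] for e in ev], float)
        ev_rec = np.asarray([e[3] for e in ev], np.int64)

        dip_seg, dip_layer = [], []
        gaba_seg, gaba_layer = [], []
        layer_index = {l: i for i, l in enumerate(self.layer_names)}
        for c in self.cells:
            if c.role != "E":
                continue
            li = layer_index[c.layer]
            for s in range(c.seg_offset, c.seg_offset + c.n_seg):
                if parent[s] >= 0 and sa["z_um"][s] != 0.0:
                    dip_seg.append(s); dip_layer.append(li)
            gaba_seg.append(c.soma_seg); gaba_layer.append(li)

        rec_idx = list(record_segments)
        if record_somas:
            rec_idx = [c.soma_seg for c in self.cells] + rec_idx

        p = self.params
        syn = p["synapses"]
        rev = p["reversal_potentials_mV"]
        ca = p["calcium"]
        return {
            "parent": parent, "g_ax": g_ax, "child_gax_sum": child_sum,
            "c_nF": sa["c_nF"], "area": sa["area"], "z_um": sa["z_um"],
            "e_leak": sa["e_leak"],
            **{f"g_{ch}": np.asarray(self._seg_gbar[ch], float)
               for ch in _cells.CHANNEL_NAMES if ch != "leak"},
            "g_leak": np.asarray(self._seg_gbar["leak"], float),
            "e_na": float(rev["na"]), "e_k": float(rev["k"]),
            "e_ca": float(rev["ca"]), "e_h": float(rev["h"]),
            "ca_tau": float(ca["tau_ms"]), "ca_rest": float(ca["rest_mM"]),
            "ca_drive_factor": 1e4 / (2 * 96485.0 * float(ca["depth_um"])),
            "syn_tau": np.array([
                [syn["ampa"]["rise_tau_ms"], syn["ampa"]["decay_tau_ms"]],
                [syn["gaba_a"]["rise_tau_ms"], syn["gaba_a"]["decay_tau_ms"]]]),
            "e_syn": np.array([syn["ampa"]["reversal_mV"],
                               syn["gaba_a"]["reversal_mV"]]),
            "fast_ampa_tau": _fast_ampa_tau(syn),
            "fast_ampa_seg": self._inh_seg_mask(),
            "ampa_ovr_seg": np.asarray(sorted(self.ampa_tau_override),
                                       np.int64),
            "ampa_ovr_tau": np.asarray(
                [self.ampa_tau_override[s]
                 for s in sorted(self.ampa_tau_override)],
                float).reshape(-1, 2),
            "delay_ms": float(syn["delivery_delay_ms"]),
            "soma_idx": np.asarray([c.soma_seg for c in self.cells], np.int64),
            "conn_ptr": conn_ptr, "conn_seg": conn_seg, "conn_w": conn_w,
            "conn_rec": conn_rec,
            "ev_time": ev_time, "ev_seg": ev_seg, "ev_w": ev_w, "ev_rec": ev_rec,
            "i_tonic": self.i_tonic.copy(),
            "inj_seg": np.empty(0, np.int64),
            "inj_traces": np.empty((0, 0)),
            "dip_seg": np.asarray(dip_seg, np.int64),
            "dip_layer": np.asarray(dip_layer, np.int64),
            "n_layers": len(self.layer_names),
            "gaba_seg": np.asarray(gaba_seg, np.int64),
            "gaba_layer": np.asarray(gaba_layer, np.int64),
            "rec_idx": np.asarray(rec_idx, np.int64),
            "v_init": float(p["v_rest_init_mV"]),
            "spike_threshold": float(p["spike_threshold_mV"]),
        }

    def run(self, duration: float = 550.0, dt: float = 0.025,
            record_segments=(), record_somas: bool = False):
        """Integrate and return a ``RunResult``."""
        from .dipole import DipoleTimeSeries
        assembled = self.assemble(record_segments, record_somas)
        out = _engine.run(assembled, duration, dt)
        dipole = DipoleTimeSeries(
            t=out["t"],
            layers={l: out["dipole"][:, i].copy()
                    for i, l in enumerate(self.layer_names)},
            metadata={"duration_ms": duration, "dt_ms": dt},
        )
        return RunResult(network=self, t=out["t"], dipole=dipole,
                         gaba_current={l: out["gaba_current"][:, i].copy()
                                       for i, l in enumerate(self.layer_names)},
                         spike_cell=out["spike_cell"],
                         spike_time=out["spike_time"],
                         v_rec=out["v_rec"], rec_idx=assembled["rec_idx"])


def build_network(layers, config: NetworkConfig,
                  params: dict | None = None) -> Network:
    """Build the laminar network restricted to ``layers`` (subset of the
    configured layers)."""
    layers = set(layers)
    unknown = layers - set(LAYERS)
    if unknown:
        raise ValueError(f"unknown layers {sorted(unknown)}")
    missing = layers - set(config.layers)
    if missing:
        raise ValueError(f"no configuration for layers {sorted(missing)}")
    sub = NetworkConfig(layers={l: config.layers[l] for l in layers})
    return Network(sub, params=params)


@dataclass
class RunResult:
    """Raw recordings from one integration."""

    network: Network
    t: np.ndarray
    dipole: "DipoleTimeSeries"          # noqa: F821
    gaba_current: dict[str, np.ndarray]
    spike_cell: np.ndarray
    spike_time: np.ndarray
    v_rec: np.ndarray
    rec_idx: np.ndarray

    def spike_times_of(self, role: str, layer: str | None = None) -> list[np.ndarray]:
        """Per-cell spike-time arrays for one population."""
        out = []
        for c in self.network.cells_of(role, layer):
            out.append(np.sort(self.spike_time[self.spike_cell == c.index]))
        return out

    def spikes_dataframe(self):
        import pandas as pd
        cells = self.network.cells
        return pd.DataFrame({
            "time_ms": self.spike_time,
            "cell": self.spike_cell,
            "role": [cells[c].role for c in self.spike_cell],
            "layer": [cells[c].layer for c in self.spike_cell],
        }).sort_values("time_ms", ignore_index=True)


def deliver_events(spike_times, t_grid, synapse: SynapseSpec,
                   weight_uS: float = 1.0) -> np.ndarray:
    """Conductance trace (uS) from presynaptic spikes through a two-exponential
    synapse: each spike adds, after the delivery delay, a transient
    ``w * f * (exp(-t/tau_d) - exp(-t/tau_r))`` normalized to peak at ``w``.
    Events superpose linearly."""
    t = np.asarray(t_grid, float)
    g = np.zeros_like(t)
    f = _engine.exp2_peak_factor(synapse.rise_tau, synapse.decay_tau)
    for ts in np.atleast_1d(np.asarray(spike_times, float)):
        tt = t - (ts + synapse.delivery_delay)
        m = tt > 0
        g[m] += weight_uS * f * (np.exp(-tt[m] / synapse.decay_tau)
                                 - np.exp(-tt[m] / synapse.rise_tau))
    return g
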