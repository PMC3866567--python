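"""Equivalent current dipole: forward model, renormalization, size extrapolation.

The longitudinal current dipole of one layer is

    Q_total(t) = sum_cells sum_segments ((v_i - v_j) / r_i) * z_i

where ``v_j`` is the voltage of the parent segment, ``r_i`` the axial
resistance between the segment centres, and ``z_i`` the signed length
component of the segment along the apical axis (positive toward the pia).
Oblique-dendrite segments have ``z_i = 0`` and contribute nothing; basket
cells are excluded.  Units: (mV / Mohm) * um = 1e-6 nAm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: per-pyramidal-cell baseline offsets removed from the raw CD series
L2_BASELINE_OFFSET_NAM = 4.43e-8
L5_BASELINE_SLOPE_NAM_PER_MS = 1.01e-10
L5_BASELINE_INTERCEPT_NAM = -4.841e-5


@dataclass
class DipoleTimeSeries:
    """Per-layer and aggregate current dipole on a fixed time grid (ms, nAm)."""

    t: np.ndarray
    layers: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, q in self.layers.items():
            q = np.asarray(q, float)
            if q.shape != self.t.shape:
                raise ValueError(f"layer {name!r}: grid mismatch")
            if not np.all(np.isfinite(q)):
                raise ValueError(f"layer {name!r}: non-finite dipole values")
            self.layers[name] = q

    @property
    def aggregate(self) -> np.ndarray:
        """Linear sum of the layer dipoles on the shared grid."""
        return np.sum(list(self.layers.values()), axis=0)

    def window(self, t_start: float, t_stop: float) -> "DipoleTimeSeries":
        m = (self.t >= t_start) & (self.t <= t_stop)
        return DipoleTimeSeries(
            t=self.t[m], layers={k: v[m] for k, v in self.layers.items()},
            metadata=dict(self.metadata))


def dipole_from_voltages(v: np.ndarray, parent: np.ndarray,
                         g_axial_uS: np.ndarray, z_um: np.ndarray) -> np.ndarray:
    """Dipole time series (nAm) from a voltage trajectory.

    ``v`` has shape (n_times, n_segments); segments with ``parent < 0`` are
    roots and contribute nothing.  The axial current from parent to segment,
    ``g_ax * (v_parent - v_seg)`` (nA), is weighted by the segment's signed
    apical-axis projection.
    """
    v = np.asarray(v, float)
    parent = np.asarray(parent)
    mask = parent >= 0
    if v.ndim != 2 or v.shape[1] != parent.shape[0]:
        raise ValueError("voltage trajectory does not cover all segments")
    dv = v[:, parent[mask]] - v[:, mask]
    return (dv * (g_axial_uS[mask] * z_um[mask])).sum(axis=1) * 1e-6


def compute_dipole(network, v_traj: np.ndarray) -> DipoleTimeSeries:
    """Per-layer dipole from a full-network voltage trajectory
    (n_times, n_segments); used for cross-checks against the online engine
    accumulation."""
    assembled = network.assemble()
    parent, g_ax, z = assembled["parent"], assembled["g_ax"], assembled["z_um"]
    n_t = v_traj.shape[0]
    layers = {}
    for layer in network.layer_names:
        q = np.zeros(n_t)
        for c in network.cells_of("E", layer):
            sl = slice(c.seg_offset, c.seg_offset + c.n_seg)
            q += dipole_from_voltages(
                v_traj[:, sl],
                np.where(parent[sl] >= 0, parent[sl] - c.seg_offset, -1),
                g_ax[sl], z[sl])
        layers[layer] = q
    return DipoleTimeSeries(t=np.arange(n_t, dtype=float), layers=layers)


def baseline_renormalize(series: DipoleTimeSeries, layer: str,
                         n_pyr: int = 100, invert: bool = False) -> DipoleTimeSeries:
    """Remove the per-cell standing baseline from one layer's CD series.

    L2/3: subtract a constant offset per pyramidal cell; L5: subtract a
    slowly drifting line per cell over the analysis interval.  The operation
    is affine; ``invert=True`` restores the original series exactly.
    """
    if layer not in series.layers:
        raise ValueError(f"series has no layer {layer!r}")
    if layer == "L2/3":
        shift = np.full_like(series.t, L2_BASELINE_OFFSET_NAM * n_pyr)
    elif layer == "L5":
        shift = (L5_BASELINE_SLOPE_NAM_PER_MS * series.t
                 + L5_BASELINE_INTERCEPT_NAM) * n_pyr
    else:
        raise ValueError(f"unknown layer {layer!r}")
    sign = +1.0 if invert else -1.0
    layers = dict(series.layers)
    layers[layer] = series.layers[layer] + sign * shift
    return DipoleTimeSeries(t=series.t, layers=layers,
                            metadata=dict(series.metadata))


def estimate_network_size(max_cd_nAm: float, n_cells: int,
                          observable_threshold_nAm: float = 10.0) -> int:
    """Order-of-magnitude pyramidal count needed for an observable dipole.

    Assumes the signal grows linearly with the participating population:
    ``n_cells * threshold / max_cd``, reported as the nearest power of ten.
    """
    if max_cd_nAm <= 0:
        raise ValueError("max_cd must be positive")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    n = n_cells * observable_threshold_nAm / max_cd_nAm
    return int(10 ** round(math.log10(n)))
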