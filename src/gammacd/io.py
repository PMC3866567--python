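"""Readers and writers for simulation products.

Formats:

* two-column delimited text for time series (``time_ms  value``), the
  format the stand-alone analysis CLI consumes;
* delimited spike lists (``time_ms  cell  role  layer``);
* delimited network edge lists (``pre  post  transmitter  weight_uS
  delay_ms``);
* one bundled HDF5 container per run holding the dipole, spikes, summary
  statistics and an embedded snapshot of the scenario configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def write_series(path, t, x, header: str = "time_ms\tvalue"):
    """Write a two-column tab-delimited time series."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValueError("need matching 1-d time and value arrays")
    np.savetxt(path, np.column_stack([t, x]), fmt="%.6g", delimiter="\t",
               header=header, comments="# ")


def read_series(path):
    """Read a two-column delimited series (whitespace or comma separated).

    Returns (t, x) float arrays; lines starting with '#' are ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"malformed series line: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise ValueError("series needs at least two samples")
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1]


def write_spikes(path, result):
    """Write a RunResult's spikes as delimited text."""
    df = result.spikes_dataframe()
    df.to_csv(path, sep="\t", index=False)


def write_edge_list(path, network):
    """Write the network's synapse edge list as delimited text."""
    df = network.edge_list()
    with open(path, "w") as fh:
        fh.write("pre\tpost\ttransmitter\tweight_uS\tdelay_ms\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.pre}\t{row.post}\t{row.transmitter}\t"
                     f"{row.weight_uS:.6g}\t{row.delay_ms:.6g}\n")


# ---------------------------------------------------------------------------
# HDF5 run bundle
# ---------------------------------------------------------------------------

def write_bundle(path, bundle):
    """Write one run bundle (see ``gammacd.scenarios.RunBundle``) to HDF5."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["config_json"] = json.dumps(bundle.config)
        h5.attrs["config_hash"] = bundle.config_hash
        h5.attrs["seed"] = bundle.seed
        h5.attrs["wall_time_s"] = bundle.wall_time_s
        h5.create_dataset("t_ms", data=bundle.t)
        grp = h5.create_group("dipole_nAm")
        for layer, q in bundle.dipole.items():
            grp.create_dataset(layer.replace("/", "_"), data=q)
        sp = h5.create_group("spikes")
        sp.create_dataset("time_ms", data=bundle.spike_time)
        sp.create_dataset("cell", data=bundle.spike_cell)
        h5.attrs["stats_json"] = json.dumps(bundle.stats)


def read_bundle(path):
    """Read a bundle written by :func:`write_bundle` into a plain dict."""
    import h5py

    out = {}
    with h5py.File(path, "r") as h5:
        out["config"] = json.loads(h5.attrs["config_json"])
        out["config_hash"] = str(h5.attrs["config_hash"])
        out["seed"] = int(h5.attrs["seed"])
        out["wall_time_s"] = float(h5.attrs["wall_time_s"])
        out["t_ms"] = h5["t_ms"][()]
        out["dipole_nAm"] = {k.replace("_", "/", 1) if k.startswith("L2")
                             else k: v[()]
                             for k, v in h5["dipole_nAm"].items()}
        out["spike_time"] = h5["spikes/time_ms"][()]
        out["spike_cell"] = h5["spikes/cell"][()]
        out["stats"] = json.loads(h5.attrs["stats_json"])
    return out
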