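"""Single-cell model: geometry, passive-cable oracle, dipole oracle, spikes."""

from __future__ import annotations

import copy

import numpy as np
import pytest
from scipy.linalg import expm

from gammacd import build_cell, detect_spikes
from gammacd.cells import integrate_cell, load_parameters
from gammacd.dipole import dipole_from_voltages

ACTIVE_CHANNELS = ("na", "k", "kdr", "km", "ca", "cat", "h", "kca")


def _passive_params(kind):
    p = copy.deepcopy(load_parameters())
    ch = p["cells"][kind]["channels"]
    for name in list(ch):
        if name in ACTIVE_CHANNELS:
            ch[name]["gbar_mS_cm2"] = 0.0
    p["cells"][kind].pop("channel_overrides", None)
    return p


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_apical_axis_length_ratio():
    l5 = build_cell("l5_pyramidal")
    l2 = build_cell("l23_pyramidal")
    assert l5.apical_axis_extent() / l2.apical_axis_extent() == pytest.approx(
        2.21, abs=1e-6)


def test_unknown_cell_kind_rejected():
    with pytest.raises((KeyError, ValueError)):
        build_cell("stellate")


# ---------------------------------------------------------------------------
# passive-cable analytic oracle
# ---------------------------------------------------------------------------

def test_passive_cable_matches_linear_system():
    """With active conductances zeroed the cell is a linear RC cable; the
    engine trajectory must match the exact matrix-exponential solution to
    within 0.5% RMS of the voltage excursion."""
    params = _passive_params("l23_pyramidal")
    model = build_cell("l23_pyramidal", params)
    segs = model.segments()
    n = len(segs)
    e_l = model.channels.leak_reversal

    out = integrate_cell(model, {"current": {"soma": 0.2}},
                         duration=60.0, dt=0.025, v_init=e_l, params=params)
    v_engine = out["v"]

    # exact solution: C dv/dt = -G (v - e_l) + b  ->  matrix exponential
    c_nF = np.array([model.cm * s.area_cm2 * 1e3 for s in segs])
    g_leak = model.segment_gbar("leak")          # absolute uS per segment
    G = np.diag(g_leak.astype(float))
    for s in segs:
        if s.parent_index >= 0:
            i, j = s.index, s.parent_index
            G[i, i] += s.g_axial_uS
            G[j, j] += s.g_axial_uS
            G[i, j] -= s.g_axial_uS
            G[j, i] -= s.g_axial_uS
    b = np.zeros(n)
    soma = next(s.index for s in segs if s.compartment == "soma")
    b[soma] = 0.2                                 # nA
    A = -G / c_nF[:, None]
    rhs = (g_leak * e_l + b) / c_nF
    t = out["t"]
    v_exact = np.empty_like(v_engine)
    v_inf = np.linalg.solve(G, g_leak * e_l + b)
    v0 = np.full(n, e_l)
    for k, tk in enumerate(t):
        v_exact[k] = v_inf + expm(A * tk) @ (v0 - v_inf)
    swing = np.max(np.abs(v_exact - e_l))
    rms = np.sqrt(np.mean((v_engine - v_exact) ** 2))
    assert rms <= 0.005 * swing


# ---------------------------------------------------------------------------
# dipole brute-force oracle and invariants
# ---------------------------------------------------------------------------

def _random_tree(rng, n=9):
    parent = np.array([-1] + [int(rng.integers(0, i)) for i in range(1, n)])
    g_ax = rng.uniform(0.01, 1.0, n)
    z = rng.uniform(-300.0, 300.0, n)
    z[0] = 0.0
    return parent, g_ax, z


def test_dipole_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    parent, g_ax, z = _random_tree(rng)
    v = rng.uniform(-80.0, 40.0, (50, parent.size))
    q = dipole_from_voltages(v, parent, g_ax, z)
    oracle = np.zeros(v.shape[0])
    for s in range(parent.size):
        if parent[s] >= 0:
            oracle += (v[:, parent[s]] - v[:, s]) * g_ax[s] * z[s] * 1e-6
    np.testing.assert_allclose(q, oracle, rtol=1e-12, atol=1e-18)


def test_dipole_linearity_and_uniform_voltage():
    rng = np.random.default_rng(1)
    parent, g_ax, z = _random_tree(rng)
    v1 = rng.uniform(-80.0, 40.0, (20, parent.size))
    v2 = rng.uniform(-80.0, 40.0, (20, parent.size))
    q = lambda v: dipole_from_voltages(v, parent, g_ax, z)
    # uniform voltage -> no axial current -> zero dipole
    np.testing.assert_allclose(q(np.full_like(v1, -65.0)), 0.0, atol=1e-18)
    # linear in the voltage field
    np.testing.assert_allclose(q(2.0 * v1 + 3.0 * v2), 2.0 * q(v1) + 3.0 * q(v2),
                               rtol=1e-10, atol=1e-18)


def test_oblique_segments_do_not_contribute():
    rng = np.random.default_rng(2)
    parent, g_ax, z = _random_tree(rng)
    v = rng.uniform(-80.0, 40.0, (20, parent.size))
    base = dipole_from_voltages(v, parent, g_ax, z)
    v_mod = v.copy()
    z_obl = z.copy()
    z_obl[3] = 0.0                    # make one segment oblique
    v_mod[:, 3] += rng.uniform(-5, 5, 20)
    # with z = 0 its voltage is irrelevant to the dipole... unless it is a
    # parent of another segment
    children = np.flatnonzero(parent == 3)
    if children.size == 0:
        np.testing.assert_allclose(
            dipole_from_voltages(v_mod, parent, g_ax, z_obl),
            dipole_from_voltages(v, parent, g_ax, z_obl))
    assert not np.allclose(base, dipole_from_voltages(v, parent, g_ax, z_obl))


# ---------------------------------------------------------------------------
# spiking behaviour
# ---------------------------------------------------------------------------

def test_resting_cell_is_silent():
    model = build_cell("l5_pyramidal")
    out = integrate_cell(model, duration=150.0)
    assert out["spike_times"].size == 0
    soma = next(s.index for s in model.segments() if s.compartment == "soma")
    assert np.all(out["v"][-100:, soma] < -50.0)


def test_driven_cell_fires_and_detect_spikes_agrees():
    model = build_cell("l5_pyramidal")
    out = integrate_cell(model, {"current": {"soma": 10.0}}, duration=200.0)
    soma = next(s.index for s in model.segments() if s.compartment == "soma")
    det = detect_spikes(out["t"], out["v"][:, soma])
    assert det.size >= 2
    assert out["spike_times"].size == det.size
    np.testing.assert_allclose(out["spike_times"], det, atol=0.5)


def test_gating_variables_stay_bounded():
    model = build_cell("l5_pyramidal")
    out = integrate_cell(model, {"current": {"soma": 10.0}}, duration=100.0)
    assert np.all(np.isfinite(out["v"]))
    assert np.all(np.abs(out["v"]) < 150.0)


def test_detect_spikes_refractory_coalescing():
    t = np.arange(0.0, 10.0, 0.1)
    v = np.full_like(t, -65.0)
    v[(t > 2.0) & (t < 2.3)] = 10.0
    v[(t > 2.5) & (t < 2.8)] = 10.0      # within 1 ms: same spike
    v[(t > 7.0) & (t < 7.3)] = 10.0
    st = detect_spikes(t, v)
    assert st.size == 2
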