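"""Network construction, weight scaling, synaptic transients, drives."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammacd import (NetworkConfig, PoissonDrive, RhythmicBurstDrive,
                     SynapseSpec, build_network, deliver_events,
                     sample_burst_events, sample_poisson_events, weight_scale)

SETTINGS = dict(max_examples=25, deadline=None)


# ---------------------------------------------------------------------------
# weight scaling
# ---------------------------------------------------------------------------

def test_weight_scale_unity_at_zero_and_e_inverse_at_lambda():
    assert weight_scale(0.0, 3.0) == pytest.approx(1.0)
    assert weight_scale(3.0, 3.0) == pytest.approx(np.exp(-1.0))
    assert weight_scale(30.0, 30.0) == pytest.approx(np.exp(-1.0))


@settings(**SETTINGS)
@given(lam=st.floats(0.5, 100.0),
       d=st.lists(st.floats(0.0, 500.0), min_size=2, max_size=10))
def test_weight_scale_monotone_decreasing(lam, d):
    d = np.sort(np.asarray(d))
    w = weight_scale(d, lam)
    assert np.all(np.diff(w) <= 1e-15)
    # underflows to exactly 0 at large d/lambda, which is acceptable
    assert np.all((w >= 0) & (w <= 1.0))


# ---------------------------------------------------------------------------
# synaptic transients
# ---------------------------------------------------------------------------

def _syn(rise=0.5, decay=5.0, delay=1.0):
    return SynapseSpec("AMPA", rise, decay, 0.0, 0.0, delay)


def test_deliver_events_peaks_at_weight():
    t = np.arange(0.0, 60.0, 0.01)
    g = deliver_events([5.0], t, _syn(), weight_uS=2.5)
    assert np.max(g) == pytest.approx(2.5, rel=1e-4)
    assert np.all(g[t <= 6.0] == 0.0)      # nothing before the delivery delay


def test_deliver_events_superposition():
    """Two spikes produce exactly the sum of the single-spike transients."""
    t = np.arange(0.0, 80.0, 0.01)
    syn = _syn()
    g12 = deliver_events([5.0, 12.0], t, syn)
    g1 = deliver_events([5.0], t, syn)
    g2 = deliver_events([12.0], t, syn)
    np.testing.assert_allclose(g12, g1 + g2, atol=1e-12)


def test_deliver_events_tail_time_constant():
    """The conductance tail decays with the synapse's decay constant."""
    t = np.arange(0.0, 120.0, 0.01)
    decay = 5.0
    g = deliver_events([0.0], t, _syn(decay=decay))
    m = (t > 30.0) & (t < 60.0)            # rise term long gone
    slope = np.polyfit(t[m], np.log(g[m]), 1)[0]
    assert -1.0 / slope == pytest.approx(decay, rel=1e-3)


def test_synapse_spec_validation():
    with pytest.raises(ValueError):
        SynapseSpec("AMPA", 5.0, 0.5, 0.0, 0.0, 1.0)   # decay <= rise


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def l5_net():
    cfg = NetworkConfig.from_regimes("l5_strong_ping")
    return build_network({"L5"}, cfg)


def test_network_population_sizes(l5_net):
    assert len(l5_net.cells_of("E", "L5")) == 100
    assert len(l5_net.cells_of("I", "L5")) == 35
    assert l5_net.n_cells == 135


def test_edge_list_structure(l5_net):
    df = l5_net.edge_list()
    assert set(df.columns) == {"pre", "post", "transmitter", "weight_uS",
                               "delay_ms"}
    assert (df.weight_uS > 0).all()
    assert set(df.transmitter) == {"AMPA", "GABA_A"}
    # strong PING has g_ii = 0: every GABA edge is I -> E
    gaba = df[df.transmitter == "GABA_A"]
    assert gaba.pre.min() >= 100 and gaba.post.max() < 100
    ampa = df[df.transmitter == "AMPA"]
    assert ampa.pre.max() < 100 and ampa.post.min() >= 100


def test_connect_rejects_excluded_motifs(l5_net):
    e = l5_net.cells_of("E", "L5")
    with pytest.raises(ValueError, match="E->E"):
        l5_net.connect(e[0], e[1], "AMPA", 1e-4, 3.0)


def test_unknown_layer_rejected():
    cfg = NetworkConfig.from_regimes("l5_strong_ping")
    with pytest.raises(ValueError, match="unknown layers"):
        build_network({"L2"}, cfg)


def test_set_ampa_kinetics_validation(l5_net):
    with pytest.raises(ValueError):
        l5_net.set_ampa_kinetics([0], 5.0, 0.5)


# ---------------------------------------------------------------------------
# drives
# ---------------------------------------------------------------------------

def test_poisson_events_reproducible_and_poisson():
    drv = PoissonDrive(rate_hz=100.0, g_max=1e-3, seed=42, layer="L5")
    a = sample_poisson_events(drv, 50, 2000.0)
    b = sample_poisson_events(drv, 50, 2000.0)
    for ea, eb in zip(a, b):
        np.testing.assert_array_equal(ea, eb)
    counts = np.array([len(e) for e in a])
    lam = 100.0 * 2.0
    # index of dispersion of Poisson counts is 1
    assert abs(np.mean(counts) - lam) < 5 * np.sqrt(lam / 50)
    assert 0.5 < np.var(counts, ddof=1) / np.mean(counts) < 2.0


def test_burst_events_cycle_means_and_spread():
    drv = RhythmicBurstDrive("proximal", f=50.0, sigma=2.5, seed=1,
                             layer="L5")
    ev = sample_burst_events(drv, 2000.0)
    assert np.all((ev >= 0) & (ev < 2000.0))
    means = np.arange(0.0, 2000.0, 20.0)
    off = ev - means[np.argmin(np.abs(ev[:, None] - means[None, :]), axis=1)]
    assert np.std(off) == pytest.approx(2.5, rel=0.2)


def test_distal_burst_lags_proximal():
    prox = RhythmicBurstDrive("proximal", f=50.0, sigma=0.0, seed=1,
                              layer="L5")
    dist = RhythmicBurstDrive("distal", f=50.0, sigma=0.0, seed=1,
                              layer="L5")
    ep = np.unique(sample_burst_events(prox, 200.0))
    ed = np.unique(sample_burst_events(dist, 200.0))
    assert ep.size == ed.size
    np.testing.assert_allclose(ed - ep, 5.0)


def test_drive_validation():
    with pytest.raises(ValueError):
        PoissonDrive(rate_hz=-1.0, g_max=1e-3, seed=0)
    with pytest.raises(ValueError):
        RhythmicBurstDrive("proximal", f=0.0, sigma=2.5, seed=0)
    with pytest.raises(ValueError):
        RhythmicBurstDrive("sideways", f=50.0, sigma=2.5, seed=0)
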