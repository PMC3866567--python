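"""Shared fixtures.

The expensive 550 ms network simulations used by the acceptance tests are
session-scoped so each regime is simulated once and reused by every test
that needs it.
"""

from __future__ import annotations

import numpy as np
import pytest

from gammacd import analysis as an
from gammacd import drives as dr
from gammacd import network as nw

DURATION = 550.0
WINDOW = (50.0, 550.0)
N_SEEDS = 5
MASTER_SEED = 20131219


def derive_seeds(master: int, n: int, label: str) -> list[int]:
    key = int.from_bytes(label.encode(), "big") % (2 ** 31)
    ss = np.random.SeedSequence(master, spawn_key=(key,))
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def window(res, layer):
    lo, hi = WINDOW
    m = (res.t >= lo) & (res.t <= hi)
    return res.t[m], res.dipole.layers[layer][m]


def e_spikes(res, n_pyr=100):
    lo, hi = WINDOW
    return res.spike_time[(res.spike_time > lo) & (res.spike_time <= hi)
                          & (res.spike_cell < n_pyr)]


def run_strong():
    cfg = nw.NetworkConfig.from_regimes("l5_strong_ping")
    net = nw.build_network({"L5"}, cfg)
    dr.attach_drives(net, [dr.TonicDrive(6.0, layer="L5")], DURATION)
    return net.run(DURATION)


def run_weak(regime, layer, rate, g, seed):
    cfg = nw.NetworkConfig.from_regimes(regime)
    net = nw.build_network({layer}, cfg)
    dr.attach_drives(net, [dr.PoissonDrive(rate, g, seed=seed, layer=layer,
                                           target="proximal")], DURATION)
    return net.run(DURATION)


def run_subthreshold(f, sigma_p, sigma_d=None, seed=0):
    cfg = nw.NetworkConfig.from_regimes("l5_weak_ping")
    net = nw.build_network({"L5"}, cfg)
    burst = [dr.RhythmicBurstDrive("proximal", f, sigma_p, seed=seed,
                                   layer="L5")]
    if sigma_d is not None:
        burst.append(dr.RhythmicBurstDrive("distal", f, sigma_d,
                                           seed=seed + 7919, layer="L5"))
    dr.attach_drives(net, burst, DURATION)
    return net.run(DURATION)


def phi_of(res, layer="L5"):
    t, q = window(res, layer)
    return an.slope_ratio_of_series(t, q).phi


def peak_power(res, f, layer="L5"):
    t, q = window(res, layer)
    _, p = an.welch_periodogram(t, q).peak(f - 15.0, f + 15.0)
    return p


# ---------------------------------------------------------------------------
# session-scoped simulations
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def strong_run():
    return run_strong()


@pytest.fixture(scope="session")
def weak_l5_runs():
    seeds = derive_seeds(MASTER_SEED, N_SEEDS, "weak-l5")
    return [run_weak("l5_weak_ping", "L5", 40.0, 0.75e-2, s) for s in seeds]


@pytest.fixture(scope="session")
def weak_l2_runs():
    seeds = derive_seeds(MASTER_SEED, N_SEEDS, "weak-l2")
    return [run_weak("l2_weak_ping", "L2/3", 140.0, 0.8e-3, s) for s in seeds]


@pytest.fixture(scope="session")
def sub_seeds():
    return derive_seeds(MASTER_SEED, N_SEEDS, "subthreshold")


@pytest.fixture(scope="session")
def sub50_tight(sub_seeds):
    return [run_subthreshold(50.0, 2.5, seed=s) for s in sub_seeds]


@pytest.fixture(scope="session")
def sub50_broad(sub_seeds):
    return [run_subthreshold(50.0, 5.0, seed=s) for s in sub_seeds]


@pytest.fixture(scope="session")
def sub80_tight(sub_seeds):
    return [run_subthreshold(80.0, 2.5, seed=s) for s in sub_seeds]


@pytest.fixture(scope="session")
def proxdist_tight(sub_seeds):
    return [run_subthreshold(50.0, 2.5, sigma_d=2.5, seed=s)
            for s in sub_seeds]


@pytest.fixture(scope="session")
def proxdist_broad(sub_seeds):
    return [run_subthreshold(50.0, 2.5, sigma_d=5.0, seed=s)
            for s in sub_seeds]
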