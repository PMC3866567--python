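"""Scenario configs, bundle/series I/O, CLI, and bit-reproducibility.

The end-to-end checks use a shortened (150 ms) strong-PING scenario so the
whole file stays fast while still exercising the real simulator.
"""

from __future__ import annotations

import json

import numpy as np
import pytest
from click.testing import CliRunner

from gammacd import (FixtureSpec, Scenario, load_config, load_shipped,
                     make_fixture, run_scenario, set_parameter,
                     shipped_scenarios, validate_config, write_config)
from gammacd import io as gio
from gammacd.cli import main as cli_main


def short_scenario(seed=3):
    return Scenario(name="short-strong", layers=["L5"],
                    network={"regimes": ["l5_strong_ping"]},
                    drives=[{"type": "tonic", "i_app": 6.0, "layer": "L5",
                             "target": "soma"}],
                    duration_ms=150.0, window_ms=(50.0, 150.0), seed=seed)


@pytest.fixture(scope="module")
def short_bundle():
    return run_scenario(short_scenario())


# ---------------------------------------------------------------------------
# scenario round-trip and validation
# ---------------------------------------------------------------------------

def test_yaml_round_trip(tmp_path):
    sc = short_scenario()
    path = tmp_path / "sc.yaml"
    write_config(sc, path)
    back = load_config(path)
    assert back.to_dict() == sc.to_dict()


def test_from_dict_rejects_unknown_and_missing_keys():
    with pytest.raises(ValueError, match="unknown scenario keys"):
        Scenario.from_dict({"name": "x", "layers": ["L5"], "network": {},
                            "colour": "blue"})
    with pytest.raises(ValueError, match="missing required"):
        Scenario.from_dict({"name": "x"})


def test_validate_config_reports_problems():
    sc = short_scenario()
    sc.layers = ["L9"]
    sc.drives = [{"type": "warble"},
                 {"type": "poisson", "rate_hz": -4.0, "g_max_uS": 1e-3}]
    sc.window_ms = (200.0, 100.0)
    problems = "\n".join(validate_config(sc))
    assert "unknown layer 'L9'" in problems
    assert "unknown type 'warble'" in problems
    assert "rate_hz" in problems
    assert "window_ms" in problems


def test_shipped_scenarios_all_valid():
    table = shipped_scenarios()
    assert len(table) >= 10
    for name in ("fig2a_strong_ping", "fig3_weak_ping", "fig6a_prox50_sp2.5",
                 "fig8a_proxdist_sd2.5"):
        assert name in table
    for name in table:
        sc = load_shipped(name)          # load_config validates
        assert sc.duration_ms == 550.0


def test_set_parameter_addressing():
    sc = short_scenario()
    sc2 = set_parameter(sc, "drives.tonic.i_app", 4.0)
    assert sc2.drives[0]["i_app"] == 4.0
    assert sc.drives[0]["i_app"] == 6.0          # original untouched
    sc3 = set_parameter(sc, "seed", 99)
    assert sc3.seed == 99
    with pytest.raises(ValueError):
        set_parameter(sc, "drives.nonexistent.sigma_ms", 1.0)


# ---------------------------------------------------------------------------
# series / spikes / bundle I/O
# ---------------------------------------------------------------------------

def test_series_round_trip(tmp_path):
    fx = make_fixture(FixtureSpec("sinusoid", duration_ms=50.0))
    path = tmp_path / "series.txt"
    gio.write_series(path, fx.t, fx.x, header="time_ms\tvalue")
    t, x = gio.read_series(path)
    # the text format stores 6 significant digits
    np.testing.assert_allclose(t, fx.t, rtol=1e-5, atol=1e-12)
    np.testing.assert_allclose(x, fx.x, rtol=1e-5, atol=1e-12)


def test_read_series_accepts_commas_and_comments(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text("# a comment\n0.0, 1.5\n0.5, 2.5\n1.0, -3.0\n")
    t, x = gio.read_series(path)
    np.testing.assert_allclose(t, [0.0, 0.5, 1.0])
    np.testing.assert_allclose(x, [1.5, 2.5, -3.0])


def test_bundle_round_trip(tmp_path, short_bundle):
    path = tmp_path / "bundle.h5"
    gio.write_bundle(path, short_bundle)
    back = gio.read_bundle(path)
    assert back["config_hash"] == short_bundle.config_hash
    assert back["seed"] == short_bundle.seed
    np.testing.assert_allclose(back["t_ms"], short_bundle.t)
    np.testing.assert_allclose(back["dipole_nAm"]["L5"],
                               short_bundle.dipole["L5"])
    assert back["stats"].keys() == short_bundle.stats.keys()


def test_spikes_and_edges_files(tmp_path, short_bundle):
    gio.write_spikes(tmp_path / "spikes.txt", short_bundle.result)
    lines = (tmp_path / "spikes.txt").read_text().strip().splitlines()
    assert len(lines) > 10
    gio.write_edge_list(tmp_path / "edges.txt", short_bundle.result.network)
    head = (tmp_path / "edges.txt").read_text().splitlines()[0]
    assert "pre" in head and "weight_uS" in head


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------

def test_bit_reproducible_given_seed(short_bundle):
    again = run_scenario(short_scenario())
    np.testing.assert_array_equal(short_bundle.dipole["L5"],
                                  again.dipole["L5"])
    np.testing.assert_array_equal(short_bundle.result.spike_time,
                                  again.result.spike_time)
    assert short_bundle.config_hash == again.config_hash


def test_stats_present(short_bundle):
    st = short_bundle.stats["L5"]
    for key in ("max_abs_cd_nAm", "e_rate_mean_hz", "welch_peak_f_hz", "phi"):
        assert key in st


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_analyze(tmp_path):
    fx = make_fixture(FixtureSpec("sinusoid", {"f_hz": 47.0},
                                  duration_ms=300.0))
    series = tmp_path / "s.txt"
    gio.write_series(series, fx.t, fx.x)
    out = tmp_path / "a.json"
    res = CliRunner().invoke(cli_main, ["analyze", "--input", str(series),
                                        "--stats", "phi,welch",
                                        "--out", str(out)])
    assert res.exit_code == 0, res.output
    data = json.loads(out.read_text())
    assert abs(data["welch"]["peak_f_hz"] - 47.0) < 2.0
    assert abs(data["phi"]["phi"] - 1.0) < 0.05


def test_cli_analyze_rejects_unknown_stat(tmp_path):
    fx = make_fixture(FixtureSpec("sinusoid", duration_ms=50.0))
    series = tmp_path / "s.txt"
    gio.write_series(series, fx.t, fx.x)
    res = CliRunner().invoke(cli_main, ["analyze", "--input", str(series),
                                        "--stats", "kurtosis"])
    assert res.exit_code != 0


def test_cli_simulate(tmp_path):
    cfg = tmp_path / "sc.yaml"
    write_config(short_scenario(), cfg)
    out = tmp_path / "run"
    res = CliRunner().invoke(cli_main, ["simulate", "--config", str(cfg),
                                        "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "bundle.h5").exists()
    assert (out / "summary.json").exists()
    summary = json.loads((out / "summary.json").read_text())
    assert summary["stats"]["L5"]["max_abs_cd_nAm"] > 0
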