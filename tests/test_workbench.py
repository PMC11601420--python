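"""Fixtures, experiment runner, CLI round trips."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import eadsim
from eadsim.cli import main as cli_main
from eadsim.fixtures import (FixtureSpec, generate_fixture,
                             reverse_engineered_map, toy_restitution_points,
                             trapezoid_trace)
from eadsim.restitution import (fit_restitution_spline, iterate_map,
                                second_iterate_fixed_points)
from eadsim.workbench import ExperimentConfig, run_experiment


class TestFixtures:
    def test_trapezoid_apd_recovered(self):
        data = generate_fixture(FixtureSpec("toy_trace",
                                            {"apd": 180.0, "n_beats": 3}))
        s = eadsim.measure_apd(data["t"], data["v"], data["stim_times"])
        assert np.allclose(s.apd, 180.0, atol=1.0)

    def test_shallow_restitution_is_period1_only(self):
        pts = toy_restitution_points(steep=False, slope=0.08)
        rmap = fit_restitution_spline(pts)
        for period in np.arange(350.0, 700.0, 25.0):
            for di0 in np.linspace(rmap.di_min, rmap.di_max, 7):
                tr = iterate_map(rmap, period, di0, n_max=400)
                assert tr.status == "converged_period1"

    def test_steep_restitution_admits_alternans(self):
        pts = toy_restitution_points(steep=True)
        rmap = fit_restitution_spline(pts)
        statuses = set()
        for period in np.arange(500.0, 900.0, 10.0):
            tr = iterate_map(rmap, period,
                             di0=0.5 * (rmap.di_min + rmap.di_max),
                             n_max=400)
            statuses.add(tr.status)
        assert "period2" in statuses

    def test_planted_orbit_is_exact(self):
        rmap, period = reverse_engineered_map(di_a=120.0, di_b=280.0,
                                              period=520.0)
        assert rmap(120.0) == pytest.approx(520.0 - 280.0, abs=1e-9)
        assert rmap(280.0) == pytest.approx(520.0 - 120.0, abs=1e-9)
        dis = [fp.di for fp in second_iterate_fixed_points(rmap, period)]
        assert min(abs(d - 120.0) for d in dis) < 1e-4
        assert min(abs(d - 280.0) for d in dis) < 1e-4

    def test_generation_is_seed_deterministic(self):
        a = generate_fixture(FixtureSpec("toy_restitution",
                                         {"noise_sd": 3.0}), seed=4)
        b = generate_fixture(FixtureSpec("toy_restitution",
                                         {"noise_sd": 3.0}), seed=4)
        assert np.array_equal(a["points"], b["points"])


class TestRunExperiment:
    def test_empty_protocol_writes_manifest_only(self, tmp_path):
        cfg = ExperimentConfig(kind="empty", outdir=str(tmp_path / "e"))
        manifest = run_experiment(cfg)
        assert manifest["complete"] and manifest["files"] == []
        assert (tmp_path / "e" / "manifest.json").exists()

    def test_rerun_reproduces_outputs(self, tmp_path, warm_kernel):
        outs = []
        for sub in ("a", "b"):
            cfg = ExperimentConfig(kind="cell_pace", mode="stochastic",
                                   nb=500, seed=12,
                                   outdir=str(tmp_path / sub),
                                   options={"cl": 400.0, "n_beats": 3})
            m = run_experiment(cfg)
            outs.append((m["config_hash"],
                         (tmp_path / sub / "trace.csv").read_bytes()))
        assert outs[0][0] == outs[1][0]
        assert outs[0][1] == outs[1][1]

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            run_experiment(ExperimentConfig(kind="nope",
                                            outdir=str(tmp_path)))

    def test_map_analysis_round_trip(self, tmp_path):
        pts = toy_restitution_points(n=16)
        cfg = ExperimentConfig(
            kind="map_analysis", outdir=str(tmp_path / "m"),
            options={"points": pts.tolist(),
                     "periods": [500.0, 600.0, 700.0]})
        manifest = run_experiment(cfg)
        assert "map_bifurcation.csv" in manifest["files"]
        df = pd.read_csv(tmp_path / "m" / "fixed_points.csv")
        assert {"period", "di", "stability", "kind"} <= set(df.columns)

    def test_figure_presets_execute_at_reduced_scale(self, tmp_path,
                                                     warm_kernel):
        from eadsim.workbench import FIGURE_PRESETS
        cfg = FIGURE_PRESETS("fig9b", str(tmp_path / "f9"), seed=1)
        manifest = run_experiment(cfg)
        assert manifest["complete"]


class TestCLI:
    def test_cell_pace_and_outputs(self, tmp_path, warm_kernel):
        runner = CliRunner()
        res = runner.invoke(cli_main,
                            ["cell-pace", "--cl", "400", "--beats", "2",
                             "--out", str(tmp_path / "cp")])
        assert res.exit_code == 0, res.output
        df = pd.read_csv(tmp_path / "cp" / "trace.csv")
        assert {"time_ms", "v_mv", "cb_um", "csrb_um", "pb"} <= \
            set(df.columns)

    def test_map_analyze_from_csv(self, tmp_path):
        pts = toy_restitution_points(n=14)
        csv = tmp_path / "pts.csv"
        np.savetxt(csv, pts, delimiter=",", header="di,apd")
        runner = CliRunner()
        res = runner.invoke(cli_main,
                            ["map-analyze", str(csv), "--out",
                             str(tmp_path / "ma"),
                             "--t-min", "500", "--t-max", "650"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "ma" / "fixed_points.csv").exists()

    def test_phase_diagram_command(self, tmp_path):
        pts = toy_restitution_points(n=14)
        csv = tmp_path / "pts.csv"
        np.savetxt(csv, pts, delimiter=",", header="di,apd")
        runner = CliRunner()
        res = runner.invoke(cli_main,
                            ["phase-diagram", str(csv), "--out",
                             str(tmp_path / "pd"), "--nt", "8",
                             "--ndi", "8"])
        assert res.exit_code == 0, res.output
        labels = np.loadtxt(tmp_path / "pd" / "phase_diagram.csv",
                            delimiter=",")
        assert labels.shape == (8, 8)

    def test_invalid_preset_exits_2(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["preset", "not-a-preset"])
        assert res.exit_code == 2

    def test_fixture_command(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main,
                            ["fixture", "--kind", "toy_restitution",
                             "--out", str(tmp_path / "fx")])
        assert res.exit_code == 0, res.output
        manifest = json.loads(
            (tmp_path / "fx" / "manifest.json").read_text())
        assert manifest["complete"]
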