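"""Experiment configuration, output writers and reproducible runs.

An :class:`ExperimentConfig` (YAML-serializable) plus the package version
determines every output file; stochastic outputs are reproduced
bit-for-bit by the recorded seed.  ``run_experiment`` executes one
experiment and writes a manifest (config hash, version, seeds, file list,
per-stage wall time) next to the data files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell import CellModel, ModelMode
from .params import default_params, ead_params, load_params
from .protocols import (dynamic_pacing_sweep, measure_apd, s1s2_restitution)
from .restitution import (fit_restitution_spline, map_bifurcation_diagram,
                          phase_diagram, second_iterate_fixed_points)
from .fixtures import FixtureSpec, generate_fixture
from .tissue import StimulusSpec, TissueGrid, run_tissue_protocol

__all__ = ["ExperimentConfig", "run_experiment", "FIGURE_PRESETS",
           "write_trace_csv", "write_field_h5"]


@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to rerun an experiment."""

    kind: str                      # cell_pace | cell_bifurcation | s1s2 |
    #                                tissue_run | map_analysis | fixture
    param_set: str = "default"     # 'default' | 'ead' | path to YAML
    mode: str = "deterministic"
    nb: int = 4000
    seed: int = 0
    options: dict = dataclasses.field(default_factory=dict)
    outdir: str = "eadsim_out"

    def params(self) -> dict:
        if self.param_set == "default":
            return default_params()
        if self.param_set == "ead":
            return ead_params()
        return load_params(self.param_set)

    def to_yaml(self) -> str:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x
        return yaml.safe_dump(clean(dataclasses.asdict(self)),
                              sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def digest(self) -> str:
        """Hash of the scientific content (output location excluded)."""
        d = yaml.safe_load(self.to_yaml())
        d.pop("outdir", None)
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def write_trace_csv(path, trace) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_field_h5(path, snapshots: np.ndarray, times: np.ndarray,
                   attrs: dict | None = None) -> None:
    """Voltage-field stacks as HDF5 with time metadata."""
    import h5py
    with h5py.File(path, "w") as f:
        d = f.create_dataset("voltage", data=snapshots)
        f.create_dataset("time_ms", data=times)
        for k, v in (attrs or {}).items():
            d.attrs[k] = v


def _cell(config: ExperimentConfig) -> CellModel:
    return CellModel(config.params(),
                     ModelMode(config.mode, nb=config.nb,
                               seed=config.seed))


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one experiment; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": yaml.safe_load(config.to_yaml()),
                "config_hash": config.digest(),
                "version": __version__,
                "seed": config.seed,
                "files": [], "stages": [], "complete": False}
    t0 = time.perf_counter()

    def stage(name):
        manifest["stages"].append({"name": name,
                                   "t_wall_s": round(time.perf_counter()
                                                     - t0, 3)})

    opts = dict(config.options)
    try:
        if config.kind == "cell_pace":
            model = _cell(config)
            cl = float(opts.get("cl", 500.0))
            n_beats = int(opts.get("n_beats", 50))
            trace = model.run_paced(cl, n_beats)
            stage("pace")
            f = out / "trace.csv"
            write_trace_csv(f, trace)
            manifest["files"].append(f.name)
            series = measure_apd(trace.t, trace.v, trace.stim_times)
            f2 = out / "apd.csv"
            series.to_frame().to_csv(f2, index=False)
            manifest["files"].append(f2.name)
        elif config.kind == "cell_bifurcation":
            model = _cell(config)
            cls = opts.get("cls") or list(np.arange(440.0, 553.0, 8.0))
            sweep = dynamic_pacing_sweep(
                model, cls, beats_per_cl=int(opts.get("beats_per_cl", 200)),
                record_last=int(opts.get("record_last", 50)),
                direction=opts.get("direction", "up"))
            stage("sweep")
            f = out / "bifurcation.csv"
            sweep.to_csv(f, index=False)
            manifest["files"].append(f.name)
        elif config.kind == "s1s2":
            model = _cell(config)
            s2s = opts.get("s2_list") or list(np.arange(260.0, 900.0, 20.0))
            df = s1s2_restitution(model, float(opts.get("s1", 500.0)), s2s,
                                  beats_s1=int(opts.get("beats_s1", 50)))
            stage("s1s2")
            f = out / "restitution.csv"
            df.to_csv(f, index=False)
            manifest["files"].append(f.name)
        elif config.kind == "tissue_run":
            nrow = int(opts.get("nrow", 25))
            ncol = int(opts.get("ncol", 25))
            grid = TissueGrid(nrow, ncol, config.params(),
                              stochastic=(config.mode == "stochastic"),
                              seed=config.seed)
            schedule = opts.get("cl_schedule") or [[420.0, 5]]
            times = []
            t = 0.0
            for cl, nb in schedule:
                times.extend(t + cl * np.arange(int(nb)))
                t = times[-1] + cl
            stim = StimulusSpec(
                rows=tuple(opts.get("stim_rows", (0, nrow))),
                cols=tuple(opts.get("stim_cols", (0, min(10, ncol)))),
                times=np.asarray(times),
                amplitude=config.params()["stim_amp"],
                duration=config.params()["stim_dur"])
            res = run_tissue_protocol(grid, stim,
                                      snap_dt=float(opts.get("snap_dt",
                                                             10.0)))
            stage("tissue")
            f = out / "apd_map.csv"
            pd.DataFrame(res.apd_map).to_csv(f, index=False)
            manifest["files"].append(f.name)
            f2 = out / "fields.h5"
            write_field_h5(f2, res.snapshots, res.snapshot_times,
                           {"nrow": nrow, "ncol": ncol})
            manifest["files"].append(f2.name)
        elif config.kind == "map_analysis":
            pts = np.asarray(opts["points"], float)
            rmap = fit_restitution_spline(
                pts, di_block=float(opts.get("di_block", 0.0)))
            periods = opts.get("periods") or list(
                np.arange(pts[:, 1].min() + pts[:, 0].min(),
                          pts[:, 1].max() + pts[:, 0].max(), 5.0))
            bif = map_bifurcation_diagram(rmap, periods)
            stage("bifurcation")
            f = out / "map_bifurcation.csv"
            bif.to_csv(f, index=False)
            manifest["files"].append(f.name)
            rows = []
            for period in periods:
                for fp in second_iterate_fixed_points(rmap, period):
                    rows.append({"period": period, "di": fp.di,
                                 "stability": fp.stability,
                                 "kind": fp.kind, "slope": fp.slope})
            f2 = out / "fixed_points.csv"
            pd.DataFrame(rows).to_csv(f2, index=False)
            manifest["files"].append(f2.name)
            stage("fixed_points")
        elif config.kind == "fixture":
            spec = FixtureSpec(kind=opts.get("fixture_kind", "toy_trace"),
                               params=opts.get("fixture_params", {}))
            data = generate_fixture(spec, seed=config.seed)
            stage("fixture")
            for key, val in data.items():
                if isinstance(val, np.ndarray):
                    f = out / f"{key}.csv"
                    np.savetxt(f, val, delimiter=",")
                    manifest["files"].append(f.name)
        elif config.kind == "empty":
            pass
        else:
            raise ValueError(f"unknown experiment kind {config.kind!r}")
        manifest["complete"] = True
    finally:
        manifest["t_total_s"] = round(time.perf_counter() - t0, 3)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


#: Reduced-scale presets mirroring the main pacing experiments; pass
#: full_scale=True for paper-scale beat counts.
def FIGURE_PRESETS(name: str, outdir: str, seed: int = 0,
                   full_scale: bool = False) -> ExperimentConfig:
    scale = 1 if full_scale else 8
    presets = {
        "fig3a": ExperimentConfig(
            kind="cell_bifurcation", param_set="ead", mode="stochastic",
            seed=seed, outdir=outdir,
            options={"beats_per_cl": max(200 // scale, 10),
                     "record_last": max(50 // scale, 5),
                     "cls": list(np.arange(440.0, 553.0, 16.0))}),
        "fig5b": ExperimentConfig(
            kind="cell_bifurcation", param_set="ead", mode="deterministic",
            seed=seed, outdir=outdir,
            options={"beats_per_cl": max(200 // scale, 10),
                     "record_last": max(50 // scale, 5),
                     "direction": "up_then_down",
                     "cls": list(np.arange(475.0, 551.0, 15.0))}),
        "fig8": ExperimentConfig(
            kind="s1s2", param_set="ead", mode="deterministic", seed=seed,
            outdir=outdir,
            options={"beats_s1": max(50 // scale, 6),
                     "s2_list": list(np.arange(280.0, 820.0, 40.0))}),
        "fig9b": ExperimentConfig(
            kind="map_analysis", param_set="ead", seed=seed, outdir=outdir,
            options={"points":
                     [[20, 182], [80, 188], [140, 194], [200, 200],
                      [260, 206], [320, 214], [360, 280], [420, 430],
                      [480, 445], [560, 455], [640, 462], [720, 468]],
                     "di_block": 25.0,
                     "periods": list(np.arange(480.0, 760.0, 10.0))}),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(presets)}")
    return presets[name]
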