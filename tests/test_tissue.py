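"""Monodomain tissue solver: splitting, boundaries, decoupled limit."""

import numpy as np
import pytest

import eadsim
from eadsim.params import SIDX
from eadsim.tissue import (StimulusSpec, TissueGrid, detect_block_and_break,
                           diffusion_substep, run_tissue_protocol,
                           step_tissue)


class TestDiffusionSubstep:
    def test_uniform_field_is_preserved(self):
        g = TissueGrid(6, 7, relax_ms=0.0)
        g.Y[:, SIDX["v"]] = -50.0
        diffusion_substep(g, 0.1)
        assert np.allclose(g.voltage_field(), -50.0, atol=1e-12)

    def test_no_flux_boundaries_conserve_total_voltage(self):
        g = TissueGrid(8, 8, relax_ms=0.0)
        rng = np.random.default_rng(0)
        g.Y[:, SIDX["v"]] = rng.uniform(-90.0, 20.0, g.ncells)
        total0 = g.Y[:, SIDX["v"]].sum()
        for _ in range(200):
            diffusion_substep(g, 0.1)
        assert g.Y[:, SIDX["v"]].sum() == pytest.approx(total0,
                                                        rel=1e-9)

    def test_single_depolarized_cell_relaxes_toward_neighbors(self):
        g = TissueGrid(5, 5, relax_ms=0.0)
        g.Y[:, SIDX["v"]] = -80.0
        c = g.cell_index(2, 2)
        g.Y[c, SIDX["v"]] = 20.0
        v0 = 20.0
        diffusion_substep(g, 0.1)
        assert g.Y[c, SIDX["v"]] < v0
        assert g.Y[g.cell_index(2, 3), SIDX["v"]] > -80.0

    def test_unstable_timestep_refused(self):
        g = TissueGrid(4, 4, relax_ms=0.0)
        with pytest.raises(ValueError):
            diffusion_substep(g, 10 * g.stability_limit())
        with pytest.raises(ValueError):
            step_tissue(g, 10 * g.stability_limit())


class TestDecoupledLimit:
    def test_dv_zero_matches_isolated_cell_bitwise(self, normal_params,
                                                   warm_kernel):
        """With DV = 0 a grid cell reproduces the single-cell trajectory
        of the matching RNG stream exactly."""
        stim_kw = dict(amplitude=normal_params["stim_amp"],
                       duration=normal_params["stim_dur"])
        g = TissueGrid(2, 2, normal_params, stochastic=True, seed=5,
                       dv=0.0)
        stim = StimulusSpec.periodic((0, 2), (0, 2), 400.0, 3, **stim_kw)
        res = run_tissue_protocol(g, stim, tend=1200.0, rec_dt=1.0,
                                  probe_cells=[0, 3])
        g1 = TissueGrid(1, 1, normal_params, stochastic=True, seed=5,
                        dv=0.0)
        stim1 = StimulusSpec.periodic((0, 1), (0, 1), 400.0, 3, **stim_kw)
        res1 = run_tissue_protocol(g1, stim1, tend=1200.0, rec_dt=1.0,
                                   probe_cells=[0])
        assert np.array_equal(res.traces[0], res1.traces[0])
        # distinct cells carry distinct streams
        assert not np.array_equal(res.traces[0], res.traces[1])

    def test_single_cell_grid_reduces_to_cell_model(self, normal_params,
                                                    warm_kernel):
        g = TissueGrid(1, 1, normal_params, stochastic=False, dv=0.0)
        stim = StimulusSpec.periodic(
            (0, 1), (0, 1), 500.0, 2,
            amplitude=normal_params["stim_amp"],
            duration=normal_params["stim_dur"])
        res = run_tissue_protocol(g, stim, tend=1000.0, probe_cells=[0])
        apd_grid = res.apd_map[1, 0]
        m = eadsim.CellModel(normal_params, "deterministic")
        m.relax(2000.0)
        tr = m.run_paced(500.0, 2)
        s = eadsim.measure_apd(tr.t, tr.v, tr.stim_times)
        assert apd_grid == pytest.approx(s.apd[1], abs=2.0)


class TestConduction:
    def test_plane_wave_speed_increases_with_coupling(self, normal_params,
                                                      warm_kernel):
        speeds = []
        for dv in (0.5e-4, 1e-4, 2e-4):
            g = TissueGrid(1, 40, normal_params, stochastic=False, dv=dv)
            stim = StimulusSpec.periodic(
                (0, 1), (0, 5), 600.0, 1,
                amplitude=normal_params["stim_amp"],
                duration=normal_params["stim_dur"])
            res = run_tissue_protocol(g, stim, tend=600.0,
                                      probe_cells=[10, 35])
            t10 = res.act_time[0, 10]
            t35 = res.act_time[0, 35]
            assert np.isfinite(t10) and np.isfinite(t35)
            speeds.append(25 * g.dx / (t35 - t10))
        assert speeds[0] > 0
        assert speeds[0] < speeds[1] < speeds[2]


class TestBlockAndBreakDetector:
    def _result(self, snapshots, act_time=None, traces=None,
                stim_times=None):
        from eadsim.tissue import TissueResult
        n = snapshots.shape[0] if snapshots.ndim == 3 else 0
        return TissueResult(
            act_time=act_time if act_time is not None
            else np.zeros((1, snapshots.shape[1] * snapshots.shape[2])),
            apd_map=np.zeros((1, snapshots.shape[1] * snapshots.shape[2])),
            traces=traces if traces is not None else np.zeros((0, 0)),
            trace_t=np.arange(traces.shape[1]) if traces is not None
            else np.empty(0),
            probe_cells=np.array([0]),
            snapshots=snapshots,
            snapshot_times=10.0 * np.arange(n),
            stim_times=stim_times if stim_times is not None
            else np.array([0.0]))

    def test_gapped_front_is_flagged(self):
        """Constructed positive control: a half-plane front with a hole."""
        frame = np.full((20, 20), -85.0)
        frame[:, :8] = 10.0            # activated region
        frame[8:12, 7] = -85.0         # gap in the front
        res = self._result(frame[None, :, :])
        ev = detect_block_and_break(res, distal_cell=0)
        assert ev["wavebreak_frames"] == [0]

    def test_intact_plane_front_is_not_flagged(self):
        frame = np.full((20, 20), -85.0)
        frame[:, :8] = 10.0
        res = self._result(frame[None, :, :])
        ev = detect_block_and_break(res, distal_cell=0)
        assert ev["wavebreak_frames"] == []

    def test_quiescent_snapshots_produce_no_events(self):
        frames = np.full((5, 10, 10), -85.0)
        act = np.full((1, 100), np.nan)
        ev = detect_block_and_break(self._result(frames, act_time=act),
                                    distal_cell=50)
        assert ev["wavebreak_frames"] == []
        assert ev["reentry_times"] == []
        assert ev["block_beats"] == [0]   # nothing activated: block

    def test_reentry_detected_from_late_upstroke(self):
        frames = np.full((1, 4, 4), -85.0)
        t = np.arange(0.0, 900.0, 1.0)
        v = np.full_like(t, -80.0)
        v[(t >= 5) & (t < 120)] = 10.0      # paced response
        v[(t >= 500) & (t < 620)] = 10.0    # unstimulated re-excitation
        res = self._result(frames, act_time=np.zeros((1, 16)),
                           traces=v[None, :], stim_times=np.array([0.0]))
        ev = detect_block_and_break(res, distal_cell=0)
        assert len(ev["reentry_times"]) == 1
        assert ev["reentry_times"][0] == pytest.approx(500.0, abs=2.0)


class TestEADAlternansInTissue:
    def test_deterministic_530_pacing_is_period2_everywhere(
            self, ead_parameters, warm_kernel):
        """In the EAD regime large deterministic tissue settles into APD
        alternans: every cell alternates long (EAD) and short beats."""
        m = eadsim.CellModel(ead_parameters, "deterministic")
        m.run_paced(530.0, 80)
        g = TissueGrid(3, 12, ead_parameters, stochastic=False,
                       relax_ms=0.0)
        g.Y[:] = m.state
        stim = StimulusSpec.periodic(
            (0, 3), (0, 12), 530.0, 8,
            amplitude=ead_parameters["stim_amp"],
            duration=ead_parameters["stim_dur"])
        res = run_tissue_protocol(g, stim, tend=8 * 530.0)
        apd = res.apd_map[2:7]          # steady beats
        # every cell alternates with a large beat-to-beat swing
        swing = np.abs(np.diff(apd, axis=0)).min(axis=0)
        assert np.isfinite(apd).all()
        assert (swing > 30.0).all()
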