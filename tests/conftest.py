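"""Shared fixtures.

Heavy simulations that several tests need (steady-state stochastic runs,
dynamic pacing sweeps, the model-derived restitution map) are computed
once per session and reused.
"""

import numpy as np
import pytest

import eadsim


@pytest.fixture(scope="session")
def normal_params():
    return eadsim.default_params()


@pytest.fixture(scope="session")
def ead_parameters():
    return eadsim.ead_params()


@pytest.fixture(scope="session")
def warm_kernel(normal_params):
    """Force numba compilation once, on a tiny run."""
    m = eadsim.CellModel(normal_params, "deterministic")
    m.run_paced(300.0, 1)
    ms = eadsim.CellModel(normal_params,
                          eadsim.ModelMode("stochastic", nb=100, seed=0))
    ms.run_paced(300.0, 1)
    return True


@pytest.fixture(scope="session")
def steady_stochastic_run(normal_params, warm_kernel):
    """Calibration-scale stochastic run: CL=500, Nb=4000, 1550 beats."""
    m = eadsim.CellModel(normal_params,
                         eadsim.ModelMode("stochastic", nb=4000, seed=2024))
    trace = m.run_paced(500.0, 1550)
    return trace


@pytest.fixture(scope="session")
def ead_sweep(ead_parameters, warm_kernel):
    """Deterministic dynamic up-sweep, reduced-inactivation model."""
    m = eadsim.CellModel(ead_parameters, "deterministic")
    cls = [440.0, 460.0, 480.0, 500.0, 520.0, 540.0, 552.0]
    return eadsim.dynamic_pacing_sweep(m, cls, beats_per_cl=200,
                                       record_last=50, direction="up")


@pytest.fixture(scope="session")
def normal_sweep(normal_params, warm_kernel):
    """Deterministic dynamic up-sweep, normal-inactivation model."""
    m = eadsim.CellModel(normal_params, "deterministic")
    cls = [440.0, 460.0, 480.0, 500.0, 520.0, 540.0, 552.0]
    return eadsim.dynamic_pacing_sweep(m, cls, beats_per_cl=200,
                                       record_last=50, direction="up")


@pytest.fixture(scope="session")
def model_restitution_map(ead_parameters, warm_kernel):
    """Cubic-spline map fit to the calibrated EAD model's S1S2 points."""
    m = eadsim.CellModel(ead_parameters, "deterministic")
    df = eadsim.s1s2_restitution(m, 500.0, np.arange(260.0, 920.0, 20.0),
                                 beats_s1=50)
    pts = df.loc[~df.blocked, ["di", "apd"]].to_numpy()
    return eadsim.fit_restitution_spline(pts)
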