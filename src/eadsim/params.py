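"""Parameter registry and state-vector layout for the myocyte model.

All model constants live in a flat float64 vector so the numba kernel can
address them by position; this module is the single source of truth for the
ordering.  Human-facing parameter sets are YAML files (see
``eadsim/paramsets/default.yaml`` and ``ead.yaml``) mapping names to values.

Units: time ms, voltage mV, concentrations uM (Ca) or mM (Na/K),
current densities uA/uF, rates 1/ms.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import yaml

#: Ordered parameter names -> kernel vector layout.
PARAM_NAMES = [
    # --- physical / extracellular ---
    "frt",        # F/(R*T) in 1/mV
    "nao", "ko", "cao", "ki",
    # --- ionic conductances (uA/uF based) ---
    "gna", "gkr", "gks", "gk1", "gtos", "gtof", "gnak", "gnaca", "gca",
    "xs2mult",
    # --- INaK / INaCa shape constants ---
    "knai", "eta", "ksat", "kmna", "kmca", "callo",
    # --- L-type Ca channel Markov model ---
    "r1", "r2",                 # C2<->O
    "a24o", "a34o",             # Ca-independent inactivation baselines
    "aca",                      # strength of Ca-induced inactivation (1/ms)
    "cth",                      # Ca-inactivation threshold (uM)
    "k42o", "k42v", "v42", "s42",   # I1 -> C2 recovery (voltage gated)
    "a45", "k54", "v54", "s54",     # I1 <-> I2 deep inactivation
    "lcc_couple_all",           # 1: all states migrate spark-on/off; 0: O only
    # --- Ca spark birth-death ---
    "nbtot",                    # number of junctional clusters Nb
    "betab",                    # spark extinction rate (1/ms)
    "alpha0",                   # recruitment scale (1/ms)
    "ksr",                      # SR-load half-saturation for recruitment (uM)
    # --- Ca cycling compartments ---
    "gb",                       # RyR cluster release conductance (1/ms)
    "vup", "kup",               # SERCA uptake Vmax (uM/ms) and K (uM)
    "tauc", "tausr",            # cytosol / SR diffusive exchange (ms)
    "vb", "vi", "vsrb", "vsri",  # relative compartment volumes
    "bufc", "bufsr",            # instantaneous buffering factors
    "gri", "cith",              # optional NJ release (default off)
    "sca", "snaca",             # current -> flux conversions (uM/ms per uA/uF)
    # --- sodium handling ---
    "conv_na",                  # current -> mM/ms conversion
    "nai_clamped",              # 1: hold Nai fixed
    # --- stimulus & numerics ---
    "stim_amp", "stim_dur",
    "dtmin", "dtmax", "dvdt_switch",
]

PIDX = {name: i for i, name in enumerate(PARAM_NAMES)}
NPAR = len(PARAM_NAMES)

#: Ordered state-variable names -> kernel vector layout.
STATE_NAMES = [
    "v", "nai",
    "m", "h", "jg",                  # INa gates
    "xr",                            # IKr activation
    "xs1", "xs2",                    # IKs activation
    "xtos", "ytos", "xtof", "ytof",  # Ito gates
    "c1", "c2", "o", "i1", "i2",     # LCC spark-off group
    "cs1", "cs2", "os_", "is1", "is2",  # LCC spark-on group
    "cb", "ci", "csrb", "csri",      # Ca compartments (uM)
    "nb",                            # spark count (stochastic) or pb (det.)
]
SIDX = {name: i for i, name in enumerate(STATE_NAMES)}
NVAR = len(STATE_NAMES)


def default_params() -> dict:
    """Calibrated default parameter set (normal Ca-induced inactivation)."""
    with importlib.resources.files("eadsim.paramsets").joinpath(
        "default.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


def ead_params() -> dict:
    """EAD-regime parameter set (reduced Ca-induced inactivation)."""
    with importlib.resources.files("eadsim.paramsets").joinpath(
        "ead.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


def load_params(path: str | Path) -> dict:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    unknown = set(d) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    return d


def save_params(d: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def params_vector(d: dict) -> np.ndarray:
    """Pack a name->value dict into the kernel parameter vector."""
    missing = set(PARAM_NAMES) - set(d)
    if missing:
        raise ValueError(f"missing parameters: {sorted(missing)}")
    vec = np.empty(NPAR, dtype=np.float64)
    for name, i in PIDX.items():
        vec[i] = float(d[name])
    return vec


def resting_state() -> np.ndarray:
    """Approximate resting state; relax with a few unstimulated seconds
    before quantitative use (CellModel handles this)."""
    y = np.zeros(NVAR, dtype=np.float64)
    y[SIDX["v"]] = -86.0
    y[SIDX["nai"]] = 12.0
    y[SIDX["m"]] = 0.001
    y[SIDX["h"]] = 0.99
    y[SIDX["jg"]] = 0.99
    y[SIDX["xr"]] = 0.01
    y[SIDX["xs1"]] = 0.02
    y[SIDX["xs2"]] = 0.02
    y[SIDX["ytos"]] = 0.99
    y[SIDX["ytof"]] = 0.99
    y[SIDX["c1"]] = 1.0
    y[SIDX["cb"]] = 0.1
    y[SIDX["ci"]] = 0.1
    y[SIDX["csrb"]] = 700.0
    y[SIDX["csri"]] = 700.0
    return y
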