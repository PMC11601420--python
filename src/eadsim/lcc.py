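"""Ten-state Markov model of the L-type Ca current.

The channel population is split into a "spark off" group (C1, C2, O, I1,
I2) facing bulk junctional Ca and a mirror "spark on" group (CS1, CS2,
OS, IS1, IS2) facing the high local Ca of an active spark.  Ca-induced
inactivation enters through the rates

    a24 = a24o + ACa * FCa(cb),   a34 = a34o + ACa * FCa(cb),

with FCa(cb) = 1 / (1 + (cth/cb)^2); spark-on channels see Ca far above
threshold, so their FCa is pinned to 1.  Channels migrate between the
groups at the spark recruitment rate alpha_b and extinction rate beta_b.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernel as K
from .params import NVAR, SIDX, PIDX, default_params, params_vector

__all__ = ["LCCState", "LCCParams", "ca_inactivation_factor",
           "inactivation_rates", "step_lcc", "lcc_current", "STATE_ORDER"]

STATE_ORDER = ("c1", "c2", "o", "i1", "i2", "cs1", "cs2", "os", "is1", "is2")
_KERNEL_KEYS = ("c1", "c2", "o", "i1", "i2", "cs1", "cs2", "os_",
                "is1", "is2")


@dataclasses.dataclass
class LCCState:
    """Occupancy fractions of the ten Markov states (sum to 1)."""

    c1: float = 1.0
    c2: float = 0.0
    o: float = 0.0
    i1: float = 0.0
    i2: float = 0.0
    cs1: float = 0.0
    cs2: float = 0.0
    os: float = 0.0
    is1: float = 0.0
    is2: float = 0.0

    def occupancies(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_ORDER])

    def total(self) -> float:
        return float(self.occupancies().sum())

    def validate(self, tol: float = 1e-9) -> None:
        occ = self.occupancies()
        if (occ < -tol).any() or (occ > 1 + tol).any():
            raise ValueError("occupancy outside [0, 1]")
        if abs(occ.sum() - 1.0) > 1e-6:
            raise ValueError("occupancies must sum to 1")


@dataclasses.dataclass
class LCCParams:
    """Rates of the LCC Markov chain (see parameter YAML for units)."""

    a24o: float = 0.002
    a34o: float = 0.002
    aca: float = 0.15        # Ca-induced inactivation strength (1/ms)
    cth: float = 0.3         # uM threshold of Ca-induced inactivation
    r1: float = 0.3
    r2: float = 3.0
    k42o: float = 0.00365
    k42v: float = 0.02
    v42: float = -30.0
    s42: float = 6.0
    a45: float = 0.004
    k54: float = 0.00465
    v54: float = -55.0
    s54: float = 6.0
    gca: float = 100.0       # current scale
    sca: float = 10.0        # uM/ms per uA/uF flux conversion
    couple_all: bool = True  # spark-group migration from all states vs O only

    def to_params_dict(self) -> dict:
        d = default_params()
        d.update(a24o=self.a24o, a34o=self.a34o, aca=self.aca, cth=self.cth,
                 r1=self.r1, r2=self.r2, k42o=self.k42o, k42v=self.k42v,
                 v42=self.v42, s42=self.s42, a45=self.a45, k54=self.k54,
                 v54=self.v54, s54=self.s54, gca=self.gca, sca=self.sca,
                 lcc_couple_all=1 if self.couple_all else 0)
        return d


def ca_inactivation_factor(cb: float, cth: float) -> float:
    """FCa(cb) = 1 / (1 + (cth/cb)^2), in (0, 1)."""
    if cb <= 0 or cth <= 0:
        raise ValueError("cb and cth must be positive")
    return float(K._fca(cb, cth))


def inactivation_rates(cb: float, params: LCCParams,
                       spark_on: bool) -> tuple[float, float]:
    """(a24, a34): spark-off channels use FCa(cb); spark-on use FCa = 1."""
    fca = 1.0 if spark_on else ca_inactivation_factor(cb, params.cth)
    return (params.a24o + params.aca * fca,
            params.a34o + params.aca * fca)


def _pack(state: LCCState, v: float, cb: float) -> np.ndarray:
    y = np.zeros(NVAR)
    y[SIDX["v"]] = v
    y[SIDX["cb"]] = cb
    for key, kkey in zip(STATE_ORDER, _KERNEL_KEYS):
        y[SIDX[kkey]] = getattr(state, key)
    return y


def step_lcc(state: LCCState, v: float, cb: float, alpha_b: float,
             beta_b: float, params: LCCParams, dt: float) -> LCCState:
    """Advance the master equation one explicit step (sum preserved)."""
    state.validate()
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    y = _pack(state, v, cb)
    p = params_vector(params.to_params_dict())
    K._step_lcc(y, p, float(alpha_b), float(beta_b), float(dt))
    vals = {key: float(y[SIDX[kkey]])
            for key, kkey in zip(STATE_ORDER, _KERNEL_KEYS)}
    out = LCCState(**vals)
    occ = out.occupancies()
    if (occ < -1e-6).any():
        raise ArithmeticError("negative occupancy; timestep too large")
    return out


def lcc_current(state: LCCState, v: float, cb: float,
                params: LCCParams, cao: float = 1.8,
                frt: float = 0.03767) -> tuple[float, float]:
    """(ICaL, JCa): whole-cell current density and matching molar flux.

    The driving force is the nonlinear constant-field expression; the
    current is proportional to the total open fraction O + OS.  JCa is the
    Ca flux into the junctional cytosol (positive inward).
    """
    po = state.o + state.os
    ghk = K._ghk(v, cb * 1e-3, cao, frt)
    ical = params.gca * po * ghk
    jca = -params.sca * ical
    return float(ical), float(jca)
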