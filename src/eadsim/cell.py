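"""Single-cell action-potential model.

Combines the rabbit ventricular ionic currents with the phenomenological
Ca-cycling subsystem (stochastic spark recruitment, four Ca compartments,
ten-state L-type channel) into one paced myocyte.  Two variants are
provided: ``stochastic`` (binomial spark counts over ``Nb`` junctional
clusters) and ``deterministic`` (the mean-field limit in which the spark
fraction obeys dpb/dt = alpha_b (1-pb) - beta_b pb).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import _kernel as K
from .params import (NVAR, SIDX, default_params, ead_params, params_vector,
                     resting_state)

__all__ = [
    "ModelMode", "IonCurrents", "PacedTrace", "CellModel",
    "total_ion_current", "calibrate", "CalibrationTarget",
]


@dataclasses.dataclass(frozen=True)
class ModelMode:
    """Simulation variant: 'stochastic' or 'deterministic'.

    ``nb`` (cluster count) and ``seed`` apply to the stochastic variant
    only; the deterministic limit ignores both.
    """

    mode: str = "deterministic"
    nb: int = 4000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def stochastic(self) -> bool:
        return self.mode == "stochastic"


@dataclasses.dataclass
class IonCurrents:
    """Membrane current densities (uA/uF); ``iion`` is their signed sum."""

    ina: float
    ikr: float
    iks: float
    ik1: float
    itos: float
    itof: float
    inak: float
    inaca: float
    ical: float
    istim: float = 0.0

    @property
    def iion(self) -> float:
        return (self.ina + self.ikr + self.iks + self.ik1 + self.itos
                + self.itof + self.inak + self.inaca + self.ical)


@dataclasses.dataclass
class PacedTrace:
    """Sampled voltage/Ca trajectory of a paced run."""

    t: np.ndarray        # ms
    v: np.ndarray        # mV
    cb: np.ndarray       # uM, junctional cytosolic Ca
    csrb: np.ndarray     # uM, junctional SR Ca
    pb: np.ndarray       # spark fraction
    stim_times: np.ndarray
    cl: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_ms": self.t, "v_mv": self.v,
                             "cb_um": self.cb, "csrb_um": self.csrb,
                             "pb": self.pb})


def total_ion_current(state: np.ndarray, params: dict) -> IonCurrents:
    """Evaluate all membrane currents at a given state vector."""
    p = params_vector(params)
    out = np.zeros(4)
    iion = K._currents(state, p, out)
    # recompute the individual K currents in numpy for reporting
    v = state[SIDX["v"]]
    nai = state[SIDX["nai"]]
    frt, ko, ki, nao = p[0], params["ko"], params["ki"], params["nao"]
    frt = params["frt"]
    ek = math.log(ko / ki) / frt
    rkr = 1.0 / (1.0 + math.exp((v + 33.0) / 22.4))
    ikr = (params["gkr"] * math.sqrt(ko / 5.4)
           * state[SIDX["xr"]] * rkr * (v - ek))
    eks = math.log((ko + 0.018 * nao) / (ki + 0.018 * nai)) / frt
    iks = params["gks"] * state[SIDX["xs1"]] * state[SIDX["xs2"]] * (v - eks)
    dvk = v - ek
    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (dvk - 59.215)))
    bk1 = ((0.4912 * math.exp(0.08032 * (dvk + 5.476))
            + math.exp(0.06175 * (dvk - 594.31)))
           / (1.0 + math.exp(-0.5143 * (dvk + 4.753))))
    ik1 = params["gk1"] * math.sqrt(ko / 5.4) * ak1 / (ak1 + bk1) * dvk
    itos = (params["gtos"] * state[SIDX["xtos"]] * state[SIDX["ytos"]]
            * (v - ek))
    itof = (params["gtof"] * state[SIDX["xtof"]] * state[SIDX["ytof"]]
            * (v - ek))
    ena = math.log(nao / nai) / frt
    ina = (params["gna"] * state[SIDX["m"]] ** 3 * state[SIDX["h"]]
           * state[SIDX["jg"]] * (v - ena))
    residual = iion - (ina + ikr + iks + ik1 + itos + itof
                       + out[1] + out[0] + out[3])
    # residual should be ~0; fold any float dust into INaK
    return IonCurrents(ina=ina, ikr=ikr, iks=iks, ik1=ik1, itos=itos,
                       itof=itof, inak=out[3] + residual, inaca=out[1],
                       ical=out[0])


class CellModel:
    """A paced ventricular myocyte.

    Parameters
    ----------
    params : dict, optional
        Full parameter dictionary (see :mod:`eadsim.params`).  Defaults to
        the calibrated normal-inactivation set.
    mode : ModelMode or str
        'deterministic' or 'stochastic'.
    """

    def __init__(self, params: dict | None = None,
                 mode: ModelMode | str = "deterministic"):
        self.params = dict(default_params() if params is None else params)
        if isinstance(mode, str):
            mode = ModelMode(mode)
        self.mode = mode
        self._p = params_vector(self.params)
        # nbtot must reflect the mode's cluster count
        from .params import PIDX
        if self.mode.stochastic:
            self._p[PIDX["nbtot"]] = float(self.mode.nb)
        self.state = resting_state()
        self._relaxed = False

    # -- construction helpers -------------------------------------------
    @classmethod
    def normal(cls, mode="deterministic", **kw) -> "CellModel":
        return cls(default_params(), mode, **kw)

    @classmethod
    def ead(cls, mode="deterministic", **kw) -> "CellModel":
        """Reduced Ca-induced inactivation (ACa = 0.09)."""
        return cls(ead_params(), mode, **kw)

    def copy(self) -> "CellModel":
        m = CellModel(self.params, self.mode)
        m.state = self.state.copy()
        m._relaxed = self._relaxed
        return m

    # -- simulation ------------------------------------------------------
    def relax(self, duration: float = 2000.0) -> None:
        """Let the cell settle at rest (deterministic, unstimulated)."""
        K.relax_cell(self.state, self._p, float(duration))
        self._relaxed = True

    def step(self, dt: float, istim: float = 0.0,
             rng_state: np.ndarray | None = None) -> float:
        """Advance one step; returns dV/dt of the step (mV/ms)."""
        if dt < 0:
            raise ValueError("dt must be nonnegative")
        if dt == 0:
            return 0.0
        if rng_state is None:
            rng_state = self._ensure_rng()
        out = np.zeros(4)
        return K._step_cell(self.state, self._p, float(dt), float(istim),
                            self.mode.stochastic, rng_state, 0, out)

    def _ensure_rng(self) -> np.ndarray:
        if not hasattr(self, "_rng_state"):
            self._rng_state = np.array(
                [K._stream_seed(self.mode.seed, 0)], dtype=np.uint64)
        return self._rng_state

    def run_paced(self, cl: float, n_beats: int,
                  record_dt: float = 1.0, cell_stream_id: int = 0,
                  relax_first: bool = True) -> PacedTrace:
        """Pace at cycle length ``cl`` for ``n_beats``; returns the trace.

        The cell state is advanced in place, so successive calls continue
        from the end of the previous protocol stage (as in dynamic pacing
        sweeps).  ``n_beats == 0`` returns an empty trace.
        """
        if n_beats > 0 and cl <= self.params["stim_dur"]:
            raise ValueError("cycle length must exceed stimulus duration")
        if relax_first and not self._relaxed:
            self.relax()
        n = int(n_beats * cl / record_dt) + 1
        rv = np.empty(n)
        rc = np.empty(n)
        rs = np.empty(n)
        rp = np.empty(n)
        if n_beats == 0:
            empty = np.empty(0)
            return PacedTrace(empty, empty, empty, empty, empty,
                              np.empty(0), cl)
        nrec = K.run_paced_cell(self.state, self._p, float(cl), int(n_beats),
                                self.mode.stochastic, self.mode.seed,
                                cell_stream_id, float(record_dt), 0.0,
                                rv, rc, rs, rp)
        t = np.arange(nrec) * record_dt
        stim_times = np.arange(n_beats) * cl
        return PacedTrace(t, rv[:nrec], rc[:nrec], rs[:nrec], rp[:nrec],
                          stim_times, cl)


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------

@dataclasses.dataclass
class CalibrationTarget:
    """One quantity the calibrated model must reproduce."""

    name: str
    evaluate: object            # callable: params dict -> float
    target: float
    tol: float
    weight: float = 1.0


def calibrate(targets: list[CalibrationTarget], free_params: list[str],
              base_params: dict | None = None, n_sweeps: int = 2,
              step: float = 0.15, seed: int = 0) -> tuple[dict, dict]:
    """Coordinate descent over multiplicative parameter moves.

    Deterministic given ``seed`` (which only fixes the parameter ordering
    shuffle).  Returns ``(best_params, report)`` where the report lists the
    residual of every target at the optimum.
    """
    params = dict(default_params() if base_params is None else base_params)
    rng = np.random.default_rng(seed)
    order = list(free_params)

    def loss(p):
        tot = 0.0
        for tg in targets:
            val = tg.evaluate(p)
            tot += tg.weight * ((val - tg.target) / tg.tol) ** 2
        return tot

    best = loss(params)
    for sweep in range(n_sweeps):
        rng.shuffle(order)
        for name in order:
            for fac in (1.0 + step, 1.0 / (1.0 + step)):
                trial = dict(params)
                trial[name] = params[name] * fac
                val = loss(trial)
                if val < best:
                    best = val
                    params = trial
        step *= 0.5
    report = {
        tg.name: {"value": float(tg.evaluate(params)),
                  "target": tg.target, "tol": tg.tol,
                  "ok": bool(abs(tg.evaluate(params) - tg.target) <= tg.tol)}
        for tg in targets
    }
    report["_loss"] = float(best)
    return params, report
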