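"""Nonlinear APD restitution map analysis.

The map is A_{n+1} = F(DI_n) with the pacing-period constraint
T = A_n + DI_n, i.e. the single-variable iteration DI_{n+1} = G(DI_n)
with G(DI) = T - F(DI).  F is an interpolating natural cubic spline fit
to measured (DI, APD) points; outside the sampled DI range it is clamped
to its endpoint values (extrapolated physiology is not trusted).  A
trajectory terminates in conduction block when DI falls below a threshold
``di_block`` (used for tissue-derived maps).

Period-doubled solutions are roots of G(G(DI)) - DI = 0; their stability
follows from |d G^2 / d DI| at the root.  A subcritical (discontinuous,
hysteretic) period-doubling transition shows up as a pair of unstable
second-iterate roots flanking the stable period-1 point below onset,
annihilating it at onset.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

__all__ = ["RestitutionMap", "MapTrajectory", "FixedPoint",
           "fit_restitution_spline", "iterate_map",
           "second_iterate_fixed_points", "map_bifurcation_diagram",
           "phase_diagram", "cobweb_trajectory", "period1_stability_loss"]

PERIOD_TOL = 1e-3      # ms, period classification tolerance
ROOT_GRID = 2000       # points for sign-change bracketing
ROOT_TOL = 1e-6        # ms, bisection tolerance


@dataclasses.dataclass
class RestitutionMap:
    """APD-vs-DI map F with block rule and clamped extrapolation."""

    spline: CubicSpline
    di_min: float
    di_max: float
    di_block: float = 0.0

    def __call__(self, di):
        clamped = np.clip(di, self.di_min, self.di_max)
        return self.spline(clamped)

    def derivative(self, di):
        """dF/dDI with the clamped-extrapolation convention (0 outside)."""
        di = np.asarray(di, float)
        inside = (di >= self.di_min) & (di <= self.di_max)
        out = np.where(inside, self.spline.derivative()(
            np.clip(di, self.di_min, self.di_max)), 0.0)
        return out if out.ndim else float(out)

    def g(self, di, period):
        return period - self(di)

    def g2(self, di, period):
        return self.g(self.g(di, period), period)

    def g2_derivative(self, di, period):
        d1 = -self.derivative(di)
        d2 = -self.derivative(self.g(di, period))
        return d2 * d1


@dataclasses.dataclass
class MapTrajectory:
    apd: np.ndarray
    di: np.ndarray
    status: str      # converged_period1 | period2 | block | max_iter


@dataclasses.dataclass
class FixedPoint:
    di: float
    stability: str   # 'stable' | 'unstable'
    kind: str        # 'period1' | 'period2-member'
    slope: float     # dG2/dDI at the root


def fit_restitution_spline(points, di_block: float = 0.0) -> RestitutionMap:
    """Interpolating natural cubic spline through (DI, APD) points."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (DI, APD) points")
    di = pts[:, 0]
    apd = pts[:, 1]
    order = np.argsort(di)
    di, apd = di[order], apd[order]
    if np.any(np.diff(di) <= 0):
        raise ValueError("DI values must be strictly increasing")
    spline = CubicSpline(di, apd, bc_type="natural")
    return RestitutionMap(spline=spline, di_min=float(di[0]),
                          di_max=float(di[-1]), di_block=di_block)


def iterate_map(rmap: RestitutionMap, period: float, di0: float,
                n_max: int = 100) -> MapTrajectory:
    """Iterate A_{n+1} = F(DI_n), DI_{n+1} = T - A_{n+1}.

    Terminates with status 'block' if DI drops below the block threshold
    (or zero); otherwise classifies the endpoint as period-1 or period-2
    by comparing the final iterates at 1e-3 ms tolerance.
    """
    if not rmap.di_min <= di0 <= rmap.di_max:
        raise ValueError(f"DI0={di0} outside map domain "
                         f"[{rmap.di_min}, {rmap.di_max}]")
    apds_l = []
    dis_l = []
    di = float(di0)
    status = "max_iter"
    for _ in range(n_max):
        a = float(rmap(di))
        di_next = period - a
        apds_l.append(a)
        dis_l.append(di_next)
        if di_next < max(rmap.di_block, 0.0):
            status = "block"
            break
        di = di_next
    apds = np.array(apds_l)
    dis = np.array(dis_l)
    if status != "block" and len(dis) >= 3:
        if abs(dis[-1] - dis[-2]) < PERIOD_TOL:
            status = "converged_period1"
        elif abs(dis[-1] - dis[-3]) < PERIOD_TOL:
            status = "period2"
    return MapTrajectory(apd=apds, di=dis, status=status)


def second_iterate_fixed_points(rmap: RestitutionMap, period: float
                                ) -> list[FixedPoint]:
    """All roots of G^2(DI) - DI = 0 on a dense grid, with stability.

    Roots that also satisfy G(DI) = DI are tagged 'period1'; the rest are
    members of period-2 orbits.
    """
    grid = np.linspace(rmap.di_min, rmap.di_max, ROOT_GRID)
    vals = rmap.g2(grid, period) - grid
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            r = brentq(lambda x: rmap.g2(x, period) - x,
                       grid[i], grid[i + 1], xtol=ROOT_TOL)
            roots.append(r)
    out = []
    for r in roots:
        if out and abs(r - out[-1].di) < 10 * ROOT_TOL:
            continue
        slope = float(rmap.g2_derivative(r, period))
        kind = ("period1"
                if abs(rmap.g(r, period) - r) < 1e-3 else "period2-member")
        out.append(FixedPoint(di=float(r),
                              stability="stable" if abs(slope) < 1
                              else "unstable",
                              kind=kind, slope=slope))
    return out


def period1_stability_loss(rmap: RestitutionMap, t_lo: float, t_hi: float,
                           dt: float = 1.0) -> float:
    """Smallest period T at which the stable period-1 point disappears.

    Scans T upward and reports the first T with no stable period-1 root
    of the second-iterate equation (the onset of the period-doubled
    regime).  Returns NaN if period-1 stays stable over the whole range.
    """
    prev_ok = None
    for period in np.arange(t_lo, t_hi + dt / 2, dt):
        fps = second_iterate_fixed_points(rmap, period)
        ok = any(f.kind == "period1" and f.stability == "stable"
                 for f in fps)
        if prev_ok and not ok:
            return float(period)
        prev_ok = ok
    return float("nan")


def map_bifurcation_diagram(rmap: RestitutionMap, periods,
                            direction: str = "both", n_iter: int = 400,
                            n_keep: int = 8, di0: float | None = None
                            ) -> "pd.DataFrame":
    """Steady-state APD values per period, sweeping T up and/or down.

    The iteration state is carried across period increments (no reset),
    which exposes hysteresis of a bistable period doubling; a block event
    restarts from the sweep's initial DI.
    """
    import pandas as pd
    periods = np.sort(np.asarray(periods, float))
    dirs = {"up": [("up", periods)], "down": [("down", periods[::-1])],
            "both": [("up", periods), ("down", periods[::-1])]}
    if direction not in dirs:
        raise ValueError(f"unknown direction {direction!r}")
    rows = []
    for tag, seq in dirs[direction]:
        di = float(np.clip(di0 if di0 is not None
                           else 0.5 * (rmap.di_min + rmap.di_max),
                           rmap.di_min, rmap.di_max))
        for period in seq:
            blocked = False
            apds = []
            for k in range(n_iter):
                a = float(rmap(di))
                di_next = period - a
                if di_next < max(rmap.di_block, 0.0):
                    blocked = True
                    di = float(np.clip(0.5 * (rmap.di_min + rmap.di_max),
                                       rmap.di_min, rmap.di_max))
                    break
                if k >= n_iter - n_keep:
                    apds.append(a)
                di = di_next
            if blocked:
                rows.append({"direction": tag, "period": period,
                             "apd": np.nan, "blocked": True})
            else:
                for a in apds:
                    rows.append({"direction": tag, "period": period,
                                 "apd": a, "blocked": False})
    return pd.DataFrame(rows)


def phase_diagram(rmap: RestitutionMap, periods, di0s,
                  n_iter: int = 100) -> np.ndarray:
    """Label matrix over (T, DI0): 0 period-1, 1 period-2, 2 block, 3 other.

    Each cell iterates the map independently for ``n_iter`` steps; block
    is terminal (reaching DI below the block threshold at any point).
    """
    periods = np.asarray(periods, float)
    di0s = np.asarray(di0s, float)
    labels = np.full((len(di0s), len(periods)), 3, dtype=np.int8)
    code = {"converged_period1": 0, "period2": 1, "block": 2,
            "max_iter": 3}
    for j, period in enumerate(periods):
        for i, di0 in enumerate(di0s):
            if not rmap.di_min <= di0 <= rmap.di_max:
                continue
            tr = iterate_map(rmap, period, di0, n_max=n_iter)
            labels[i, j] = code[tr.status]
    return labels


def cobweb_trajectory(rmap: RestitutionMap, period: float, di0: float,
                      n: int) -> np.ndarray:
    """Cobweb polyline [(di, apd), ...] tracing ``n`` map iterations.

    Alternates vertical segments (up to the curve F) with diagonal moves
    to the next DI; endpoints coincide with :func:`iterate_map` output.
    """
    pts = [(di0, 0.0)]
    di = float(di0)
    for _ in range(n):
        a = float(rmap(di))
        pts.append((di, a))            # rise to the curve
        di_next = period - a
        pts.append((di_next, a))       # carry APD to the new DI
        if di_next < max(rmap.di_block, 0.0):
            break
        di = di_next
    return np.asarray(pts)
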