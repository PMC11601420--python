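"""Synthetic fixtures with analytically known answers.

These generators produce inputs whose ground truth is known by
construction: trapezoid action potentials with exact threshold-crossing
times, toy restitution curves with a steep sigmoidal rise mimicking the
onset of plateau prolongation, and restitution maps reverse-engineered to
contain a planted period-2 orbit.  They back the oracle tests and the
``fixture`` CLI subcommand.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .restitution import RestitutionMap, fit_restitution_spline

__all__ = ["FixtureSpec", "generate_fixture", "trapezoid_trace",
           "toy_restitution_points", "reverse_engineered_map"]


@dataclasses.dataclass
class FixtureSpec:
    kind: str                  # toy_trace | toy_restitution | reverse_engineered_map
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("toy_trace", "toy_restitution",
                             "reverse_engineered_map"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def trapezoid_trace(cl: float = 500.0, n_beats: int = 5,
                    apd: float = 200.0, v_rest: float = -85.0,
                    v_peak: float = 20.0, rise_ms: float = 1.0,
                    fall_ms: float = 1.0, dt: float = 0.5,
                    noise_sd: float = 0.0, seed: int = 0):
    """Trapezoid APs: rest -> fast rise -> plateau -> fast fall.

    The downward crossing of any threshold between v_rest and v_peak
    occurs ``apd`` plus an interpolatable fraction of ``fall_ms`` after
    the upstroke, so measured APDs have closed-form expected values.
    Returns (t, v, stim_times).
    """
    t = np.arange(0.0, cl * n_beats, dt)
    v = np.full_like(t, v_rest)
    for b in range(n_beats):
        t0 = b * cl
        tb = t - t0
        rising = (tb >= 0) & (tb < rise_ms)
        v[rising] = v_rest + (v_peak - v_rest) * tb[rising] / rise_ms
        plateau = (tb >= rise_ms) & (tb < apd)
        v[plateau] = v_peak
        falling = (tb >= apd) & (tb < apd + fall_ms)
        v[falling] = v_peak + (v_rest - v_peak) * (tb[falling] - apd) / fall_ms
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return t, v, np.arange(n_beats) * cl


def toy_restitution_points(n: int = 25, di_min: float = 20.0,
                           di_max: float = 600.0, apd_base: float = 180.0,
                           apd_rise: float = 230.0, di_mid: float = 360.0,
                           width: float = 12.0, slope: float = 0.08,
                           steep: bool = True, seed: int = 0,
                           noise_sd: float = 0.0) -> np.ndarray:
    """(DI, APD) points: gentle growth then an abrupt sigmoidal step.

    With ``steep=False`` the step is removed, leaving a shallow monotone
    curve whose map slope stays below one (a gradual, supercritical
    alternans onset fixture for contrast).
    """
    di = np.linspace(di_min, di_max, n)
    apd = apd_base + slope * di
    if steep:
        apd = apd + apd_rise / (1.0 + np.exp(-(di - di_mid) / width))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        apd = apd + rng.normal(0.0, noise_sd, size=apd.shape)
    return np.column_stack([di, apd])


def reverse_engineered_map(di_a: float = 100.0, di_b: float = 300.0,
                           period: float = 500.0,
                           di_lo: float = 20.0, di_hi: float = 450.0,
                           ) -> tuple[RestitutionMap, float]:
    """A cubic-spline map with an exact planted period-2 orbit.

    The orbit {di_a, di_b} at pacing period ``period`` satisfies
    G(di_a) = di_b and G(di_b) = di_a, i.e. F(di_a) = period - di_b and
    F(di_b) = period - di_a.  Two outer anchor points complete the four
    knots of the natural cubic spline.  Returns (map, period).
    """
    if not di_lo < di_a < di_b < di_hi:
        raise ValueError("need di_lo < di_a < di_b < di_hi")
    fa = period - di_b
    fb = period - di_a
    # outer anchors chosen to keep F monotone increasing
    pts = np.array([
        [di_lo, fa - 0.3 * (di_a - di_lo)],
        [di_a, fa],
        [di_b, fb],
        [di_hi, fb + 0.3 * (di_hi - di_b)],
    ])
    return fit_restitution_spline(pts), period


def generate_fixture(spec: FixtureSpec, seed: int = 0) -> dict:
    """Materialize a fixture; generation is deterministic given seed."""
    p = dict(spec.params)
    p.setdefault("seed", seed)
    if spec.kind == "toy_trace":
        t, v, stim = trapezoid_trace(**p)
        return {"t": t, "v": v, "stim_times": stim}
    if spec.kind == "toy_restitution":
        return {"points": toy_restitution_points(**p)}
    p.pop("seed")
    rmap, period = reverse_engineered_map(**p)
    return {"map": rmap, "period": period}
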