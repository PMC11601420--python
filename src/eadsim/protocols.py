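"""Pacing protocols and APD measurement.

APD is measured from the upstroke (first upward crossing of -20 mV within
a short window after a stimulus) to the downward crossing of either a
fixed voltage Vc = -40 mV or the 90 %-repolarization level of that beat.
Beats whose voltage never recrosses before the next stimulus are censored:
their APD is set to the full interval and flagged, and they are excluded
from mean/sigma (population convention) but counted.

An early afterdepolarization is scored on a beat when the plateau shows a
local minimum followed by a local maximum above -40 mV with prominence of
at least 2 mV (a "notch"), which formalizes the characteristic secondary
depolarization without counting it as a new upstroke.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = ["APDSeries", "ProtocolSpec", "measure_apd", "apd_statistics",
           "detect_ead_beats", "dynamic_pacing_sweep", "s1s2_restitution",
           "electrotonic_length", "EAD_PROMINENCE_MV", "EAD_FLOOR_MV"]

EAD_PROMINENCE_MV = 2.0
EAD_FLOOR_MV = -40.0
UPSTROKE_MV = -20.0
UPSTROKE_WINDOW_MS = 10.0


@dataclasses.dataclass
class APDSeries:
    """Per-beat APD/DI measurements."""

    apd: np.ndarray            # ms (censored beats: full interval)
    di: np.ndarray             # ms, NaN for last beat / censored
    beat: np.ndarray           # beat index
    censored: np.ndarray       # bool
    capture_failure: np.ndarray  # bool, no upstroke for this stimulus
    threshold: str             # description of the threshold used
    upstroke_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beat": self.beat, "apd_ms": self.apd,
                             "di_ms": self.di, "censored": self.censored,
                             "capture_failure": self.capture_failure})


@dataclasses.dataclass
class ProtocolSpec:
    """A pacing protocol: steady, dynamic sweep, or S1S2."""

    kind: str                      # 'steady' | 'dynamic_sweep' | 's1s2'
    cls: list = dataclasses.field(default_factory=list)
    beats_per_stage: int = 200
    beats_recorded: int = 50
    direction: str = "up"          # sweep ordering

    def __post_init__(self):
        if self.kind not in ("steady", "dynamic_sweep", "s1s2"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.beats_recorded > self.beats_per_stage:
            raise ValueError("beats_recorded must not exceed "
                             "beats_per_stage")


def _cross_down(t, v, thr, i0):
    """Interpolated time of the first downward crossing of thr after i0."""
    seg = v[i0:]
    idx = np.where((seg[:-1] >= thr) & (seg[1:] < thr))[0]
    if len(idx) == 0:
        return None
    i = i0 + idx[0]
    frac = (v[i] - thr) / (v[i] - v[i + 1])
    return t[i] + frac * (t[i + 1] - t[i])


def _cross_up(t, v, thr, i0, i1):
    seg = v[i0:i1]
    idx = np.where((seg[:-1] < thr) & (seg[1:] >= thr))[0]
    if len(idx) == 0:
        return None
    i = i0 + idx[0]
    frac = (thr - v[i]) / (v[i + 1] - v[i])
    return t[i] + frac * (t[i + 1] - t[i])


def measure_apd(t: np.ndarray, v: np.ndarray, stim_times: np.ndarray,
                threshold_mode: str = "fixed_mv", vc: float = -40.0,
                percent_repol: float = 90.0) -> APDSeries:
    """Per-beat APD and DI from a sampled voltage trace.

    ``threshold_mode`` is 'fixed_mv' (downward crossing of ``vc``) or
    'percent_repol' (crossing of the per-beat level
    Vpeak - fraction * (Vpeak - Vtakeoff), e.g. APD90).
    Sampling must be at most 1 ms; crossings are linearly interpolated.
    """
    if threshold_mode not in ("fixed_mv", "percent_repol"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    stim_times = np.asarray(stim_times, float)
    nb = len(stim_times)
    apd = np.full(nb, np.nan)
    di = np.full(nb, np.nan)
    censored = np.zeros(nb, bool)
    capture = np.zeros(nb, bool)
    upstrokes = np.full(nb, np.nan)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    rep_times = np.full(nb, np.nan)

    for b, ts in enumerate(stim_times):
        i0 = int(np.searchsorted(t, ts))
        iw = int(np.searchsorted(t, ts + UPSTROKE_WINDOW_MS))
        tup = _cross_up(t, v, UPSTROKE_MV, max(i0 - 1, 0), min(iw + 1,
                                                               len(t)))
        if tup is None:
            capture[b] = True
            continue
        upstrokes[b] = tup
        t_end = stim_times[b + 1] if b + 1 < nb else t[-1]
        iup = int(np.searchsorted(t, tup))
        iend = int(np.searchsorted(t, t_end))
        if threshold_mode == "fixed_mv":
            thr = vc
        else:
            vpeak = v[iup:iend].max() if iend > iup else v[iup]
            vtake = v[max(i0 - 1, 0)]
            thr = vpeak - percent_repol / 100.0 * (vpeak - vtake)
        tcross = _cross_down(t, v, thr, iup)
        if tcross is None or tcross > t_end:
            apd[b] = t_end - tup
            censored[b] = True
        else:
            apd[b] = tcross - tup
            rep_times[b] = tcross

    for b in range(nb - 1):
        if not censored[b] and not capture[b] and not capture[b + 1]:
            if not math.isnan(rep_times[b]) and not math.isnan(
                    upstrokes[b + 1]):
                di[b] = upstrokes[b + 1] - rep_times[b]

    desc = (f"fixed {vc} mV" if threshold_mode == "fixed_mv"
            else f"{percent_repol:.0f}% repolarization")
    return APDSeries(apd=apd, di=di, beat=np.arange(nb), censored=censored,
                     capture_failure=capture, threshold=desc,
                     upstroke_times=upstrokes)


def apd_statistics(series: APDSeries) -> tuple[float, float, float]:
    """(mean ms, population sigma ms, cv %) over uncensored captured beats."""
    ok = ~series.censored & ~series.capture_failure
    vals = series.apd[ok]
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need at least two uncensored beats")
    mean = float(vals.mean())
    sigma = float(vals.std())       # population convention
    return mean, sigma, 100.0 * sigma / mean


def detect_ead_beats(t: np.ndarray, v: np.ndarray, stim_times: np.ndarray,
                     prominence: float = EAD_PROMINENCE_MV,
                     floor: float = EAD_FLOOR_MV) -> np.ndarray:
    """Boolean flag per beat: does the plateau carry an EAD notch?"""
    stim_times = np.asarray(stim_times, float)
    nb = len(stim_times)
    flags = np.zeros(nb, bool)
    for b, ts in enumerate(stim_times):
        i0 = int(np.searchsorted(t, ts))
        i1 = int(np.searchsorted(t, stim_times[b + 1])) if b + 1 < nb \
            else len(t)
        seg = v[i0:i1]
        if len(seg) < 5:
            continue
        im = int(np.argmax(seg))
        pk, _ = find_peaks(seg[im:], prominence=prominence, height=floor)
        flags[b] = len(pk) > 0
    return flags


def dynamic_pacing_sweep(model, cls, beats_per_cl: int = 200,
                         record_last: int = 50,
                         direction: str = "up") -> pd.DataFrame:
    """Dynamic pacing protocol: state carried across CL stages (no reset).

    Returns a tidy frame (direction, cl, beat, apd, di, censored, ead)
    with ``record_last`` beats per CL per direction.  ``direction`` is
    'up', 'down' or 'up_then_down'.
    """
    cls = sorted(float(c) for c in cls)
    stages = {"up": [("up", cls)], "down": [("down", cls[::-1])],
              "up_then_down": [("up", cls), ("down", cls[::-1])]}
    if direction not in stages:
        raise ValueError(f"unknown direction {direction!r}")
    rows = []
    for tag, seq in stages[direction]:
        for cl in seq:
            trace = model.run_paced(cl, beats_per_cl)
            series = measure_apd(trace.t, trace.v, trace.stim_times)
            eads = detect_ead_beats(trace.t, trace.v, trace.stim_times)
            sl = slice(beats_per_cl - record_last, beats_per_cl)
            for b in range(*sl.indices(beats_per_cl)):
                rows.append({"direction": tag, "cl": cl, "beat": b,
                             "apd": series.apd[b], "di": series.di[b],
                             "censored": bool(series.censored[b]),
                             "capture_failure":
                                 bool(series.capture_failure[b]),
                             "ead": bool(eads[b])})
    return pd.DataFrame(rows)


def alternans_ranges(sweep: pd.DataFrame, spread_ms: float = 5.0) -> dict:
    """CLs showing APD alternans per direction (APD spread > spread_ms)."""
    out = {}
    for tag, g in sweep.groupby("direction"):
        cls = []
        for cl, gg in g.groupby("cl"):
            vals = gg.loc[~gg.censored, "apd"].to_numpy()
            if len(vals) >= 4 and vals.max() - vals.min() > spread_ms:
                cls.append(cl)
        out[tag] = sorted(cls)
    return out


def s1s2_restitution(model, s1: float, s2_list, beats_s1: int = 50,
                     quiet_ms: float = 900.0) -> pd.DataFrame:
    """S1S2 restitution: (DI, APD) of the S2 beat for each S2 interval.

    The model is paced to steady state at S1 once; every S2 trial restarts
    from that stored state, so trials are independent.  S2 beats that fail
    to elicit an action potential are recorded with ``blocked=True``.
    """
    model.run_paced(s1, beats_s1)
    stored = model.copy()
    rows = []
    for s2 in sorted(float(x) for x in s2_list):
        m = stored.copy()
        tr1 = m.run_paced(s2, 1, relax_first=False)     # final S1 beat
        tr2 = m.run_paced(quiet_ms, 1, relax_first=False)  # the S2 beat
        t = np.concatenate([tr1.t, tr2.t + s2])
        v = np.concatenate([tr1.v, tr2.v])
        stim = np.array([0.0, s2])
        series = measure_apd(t, v, stim)
        if series.capture_failure[0] or series.censored[0]:
            continue     # S1 beat did not repolarize before the S2
        blocked = bool(series.capture_failure[1])
        rows.append({"s2": s2, "di": series.di[0],
                     "apd": np.nan if blocked else series.apd[1],
                     "blocked": blocked})
    return pd.DataFrame(rows)


def electrotonic_length(dv: float, period: float) -> float:
    """Length scale of electrotonic averaging, sqrt(DV * T) (cm)."""
    if dv < 0 or period < 0:
        raise ValueError("DV and T must be nonnegative")
    return math.sqrt(dv * period)
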