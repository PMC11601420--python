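"""Numba-compiled core: ionic currents, LCC Markov chain, Ca cycling,
stochastic spark birth-death, single-cell and tissue integrators.

Everything operates on flat float64 state/parameter vectors whose layout is
defined in :mod:`eadsim.params`.  Each cell owns a counter-based RNG stream
(splitmix64) keyed by (seed, cell id), so stochastic tissue runs are
reproducible and independent of traversal order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import PARAM_NAMES, STATE_NAMES

# Expose vector layouts to numba as compile-time integer globals
# (P_<name> for parameters, S_<name> for state variables).
for _i, _n in enumerate(PARAM_NAMES):
    globals()["P_" + _n.upper()] = _i
for _i, _n in enumerate(STATE_NAMES):
    globals()["S_" + _n.rstrip("_").upper()] = _i

_U64 = np.uint64
_GOLD = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0


# ----------------------------------------------------------------------
# counter-based RNG (splitmix64) + exact binomial sampling
# ----------------------------------------------------------------------

@njit(cache=True)
def _stream_seed(seed, cell_id):
    """Initial splitmix64 state for stream (seed, cell_id)."""
    z = (_U64(seed) + _U64(1)) * _MIX1 + (_U64(cell_id) + _U64(1)) * _MIX2
    # one warm-up scramble
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return z ^ (z >> _U64(31))


@njit(cache=True)
def _uniform(rs, i):
    """Next uniform in [0, 1) from stream i; advances the stream."""
    rs[i] = rs[i] + _GOLD
    z = rs[i]
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    z = z ^ (z >> _U64(31))
    return float(z >> _U64(11)) * _INV53


@njit(cache=True)
def _binomial(rs, i, n, p):
    """Exact Binomial(n, p) draw by CDF inversion (one uniform per draw)."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    if p > 0.5:
        return n - _binomial(rs, i, n, 1.0 - p)
    u = _uniform(rs, i)
    # pmf recurrence from k = 0
    q = 1.0 - p
    pmf = math.exp(n * math.log(q))
    cdf = pmf
    k = 0
    ratio = p / q
    while u > cdf and k < n:
        pmf *= (n - k) * ratio / (k + 1)
        k += 1
        cdf += pmf
    return k


# ----------------------------------------------------------------------
# ionic current formulations (rabbit ventricular, Mahajan-style)
# ----------------------------------------------------------------------

@njit(cache=True)
def _ina_gates(v):
    """Fast-Na gate rates (alpha, beta) for m, h, j."""
    x = v + 47.13
    if abs(x) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * x / (1.0 - math.exp(-0.1 * x))
    bm = 0.08 * math.exp(-v / 11.0)
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = (0.3 * math.exp(-2.535e-7 * v)
              / (1.0 + math.exp(-0.1 * (v + 32.0))))
    else:
        ah = 0.135 * math.exp(-(80.0 + v) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = ((-1.2714e5 * math.exp(0.2444 * v)
               - 3.474e-5 * math.exp(-0.04391 * v)) * (v + 37.78)
              / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = (0.1212 * math.exp(-0.01052 * v)
              / (1.0 + math.exp(-0.1378 * (v + 40.14))))
    return am, bm, ah, bh, aj, bj


@njit(cache=True)
def _fca(cb, cth):
    """Ca-induced inactivation factor 1/(1+(cth/cb)^2)."""
    r = cth / cb
    return 1.0 / (1.0 + r * r)


@njit(cache=True)
def _ghk(v, cbm, cao, frt):
    """Constant-field Ca driving force (mM); cbm is subspace Ca in mM."""
    za = 2.0 * v * frt
    if abs(za) < 1e-4:
        return 2.0 * (cbm - 0.341 * cao) * (1.0 + 0.5 * za)
    ez = math.exp(za)
    return 2.0 * za * (cbm * ez - 0.341 * cao) / (ez - 1.0)


@njit(cache=True)
def _rush_larsen(y, yinf, tau, dt):
    return yinf + (y - yinf) * math.exp(-dt / tau)


@njit(cache=True)
def _currents(y, p, ical_out):
    """All membrane currents at the present state.

    Returns total Iion (uA/uF); ical_out[0] = ICaL, ical_out[1] = INaCa
    (needed by the Ca fluxes).
    """
    v = y[S_V]
    nai = y[S_NAI]
    cb = y[S_CB]
    ci = y[S_CI]
    frt = p[P_FRT]
    ko = p[P_KO]
    ki = p[P_KI]
    nao = p[P_NAO]
    cao = p[P_CAO]

    ek = math.log(ko / ki) / frt
    ena = math.log(nao / nai) / frt

    # INa
    ina = p[P_GNA] * y[S_M] ** 3 * y[S_H] * y[S_JG] * (v - ena)

    # IKr
    rkr = 1.0 / (1.0 + math.exp((v + 33.0) / 22.4))
    ikr = p[P_GKR] * math.sqrt(ko / 5.4) * y[S_XR] * rkr * (v - ek)

    # IKs
    eks = math.log((ko + 0.018 * nao) / (ki + 0.018 * nai)) / frt
    iks = p[P_GKS] * y[S_XS1] * y[S_XS2] * (v - eks)

    # IK1
    dvk = v - ek
    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (dvk - 59.215)))
    bk1 = ((0.4912 * math.exp(0.08032 * (dvk + 5.476))
            + math.exp(0.06175 * (dvk - 594.31)))
           / (1.0 + math.exp(-0.5143 * (dvk + 4.753))))
    ik1 = p[P_GK1] * math.sqrt(ko / 5.4) * ak1 / (ak1 + bk1) * dvk

    # Ito (slow + fast)
    itos = p[P_GTOS] * y[S_XTOS] * y[S_YTOS] * (v - ek)
    itof = p[P_GTOF] * y[S_XTOF] * y[S_YTOF] * (v - ek)

    # INaK
    sig = (math.exp(nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v * frt)
                  + 0.0365 * sig * math.exp(-v * frt))
    inak = (p[P_GNAK] * fnak * (nai / (nai + p[P_KNAI]))
            * (ko / (ko + 1.5)))

    # INaCa (driven by junctional cytosolic Ca)
    cbm = cb * 1e-3
    z = v * frt
    eta = p[P_ETA]
    e1 = math.exp(eta * z)
    e2 = math.exp((eta - 1.0) * z)
    num = e1 * nai ** 3 * cao - e2 * nao ** 3 * cbm
    den = ((p[P_KMNA] ** 3 + nao ** 3) * (p[P_KMCA] + cao)
           * (1.0 + p[P_KSAT] * e2))
    allo = 1.0 / (1.0 + (p[P_CALLO] / cb) ** 2)
    inaca = p[P_GNACA] * allo * num / den

    # ICaL via constant-field driving force and Markov open fractions
    po = y[S_O] + y[S_OS]
    ical = p[P_GCA] * po * _ghk(v, cbm, cao, frt)

    ical_out[0] = ical
    ical_out[1] = inaca
    ical_out[2] = ina
    ical_out[3] = inak
    return ina + ikr + iks + ik1 + itos + itof + inak + inaca + ical


@njit(cache=True)
def _step_gates(y, p, dt):
    """Advance HH-type gates one step (Rush-Larsen, exact for frozen V)."""
    v = y[S_V]
    am, bm, ah, bh, aj, bj = _ina_gates(v)
    y[S_M] = _rush_larsen(y[S_M], am / (am + bm), 1.0 / (am + bm), dt)
    y[S_H] = _rush_larsen(y[S_H], ah / (ah + bh), 1.0 / (ah + bh), dt)
    y[S_JG] = _rush_larsen(y[S_JG], aj / (aj + bj), 1.0 / (aj + bj), dt)

    # IKr activation
    xrinf = 1.0 / (1.0 + math.exp(-(v + 50.0) / 7.5))
    x1 = v + 7.0
    if abs(x1) < 1e-6:
        k1 = 1.38e-3 / 0.123
    else:
        k1 = 1.38e-3 * x1 / (1.0 - math.exp(-0.123 * x1))
    x2 = v + 10.0
    if abs(x2) < 1e-6:
        k2 = 6.1e-4 / 0.145
    else:
        k2 = 6.1e-4 * x2 / (math.exp(0.145 * x2) - 1.0)
    y[S_XR] = _rush_larsen(y[S_XR], xrinf, 1.0 / (k1 + k2), dt)

    # IKs activation (two gates, tau_xs2 = 4 tau_xs1)
    xsinf = 1.0 / (1.0 + math.exp(-(v - 1.5) / 16.7))
    x3 = v + 30.0
    if abs(x3) < 1e-6:
        a = 7.19e-5 / 0.148
        b = 1.31e-4 / 0.0687
    else:
        a = 7.19e-5 * x3 / (1.0 - math.exp(-0.148 * x3))
        b = 1.31e-4 * x3 / (math.exp(0.0687 * x3) - 1.0)
    tauxs = 1.0 / (a + b)
    y[S_XS1] = _rush_larsen(y[S_XS1], xsinf, tauxs, dt)
    y[S_XS2] = _rush_larsen(y[S_XS2], xsinf, p[P_XS2MULT] * tauxs, dt)

    # Ito gates
    xtinf = 1.0 / (1.0 + math.exp(-(v + 3.0) / 15.0))
    ytinf = 1.0 / (1.0 + math.exp((v + 33.5) / 10.0))
    txs = 9.0 / (1.0 + math.exp((v + 3.0) / 15.0)) + 0.5
    tys = 3000.0 / (1.0 + math.exp((v + 60.0) / 10.0)) + 30.0
    txf = 3.5 * math.exp(-(v / 30.0) ** 2) + 1.5
    tyf = 20.0 / (1.0 + math.exp((v + 33.5) / 10.0)) + 20.0
    y[S_XTOS] = _rush_larsen(y[S_XTOS], xtinf, txs, dt)
    y[S_YTOS] = _rush_larsen(y[S_YTOS], ytinf, tys, dt)
    y[S_XTOF] = _rush_larsen(y[S_XTOF], xtinf, txf, dt)
    y[S_YTOF] = _rush_larsen(y[S_YTOF], ytinf, tyf, dt)


@njit(cache=True)
def _lcc_rates(v, p):
    """Voltage-dependent LCC transition rates (shared by both groups)."""
    dinf = 1.0 / (1.0 + math.exp(-(v + 10.0) / 6.24))
    x = v + 10.0
    if abs(x) < 1e-6:
        taud = dinf / (0.035 * 6.24)
    else:
        taud = dinf * (1.0 - math.exp(-x / 6.24)) / (0.035 * x)
    a12 = dinf / taud
    a21 = (1.0 - dinf) / taud
    a42 = p[P_K42O] + p[P_K42V] / (1.0 + math.exp((v - p[P_V42]) / p[P_S42]))
    a54 = p[P_K54] / (1.0 + math.exp((v - p[P_V54]) / p[P_S54]))
    return a12, a21, a42, a54


@njit(cache=True)
def _step_lcc(y, p, alpha_b, beta_b, dt):
    """Advance the ten-state LCC master equation one explicit step."""
    v = y[S_V]
    cb = y[S_CB]
    a12, a21, a42, a54 = _lcc_rates(v, p)
    r1 = p[P_R1]
    r2 = p[P_R2]
    a45 = p[P_A45]
    fca = _fca(cb, p[P_CTH])
    a24 = p[P_A24O] + p[P_ACA] * fca
    a34 = p[P_A34O] + p[P_ACA] * fca
    # spark-on group: local Ca >> cth, FCa = 1
    a24s = p[P_A24O] + p[P_ACA]
    a34s = p[P_A34O] + p[P_ACA]

    c1 = y[S_C1]
    c2 = y[S_C2]
    o = y[S_O]
    i1 = y[S_I1]
    i2 = y[S_I2]
    cs1 = y[S_CS1]
    cs2 = y[S_CS2]
    os = y[S_OS]
    is1 = y[S_IS1]
    is2 = y[S_IS2]

    couple_all = p[P_LCC_COUPLE_ALL] > 0.5
    if couple_all:
        ab_c = alpha_b
    else:
        ab_c = 0.0

    dc1 = a21 * c2 - a12 * c1 + beta_b * cs1 - ab_c * c1
    dc2 = (a12 * c1 + r2 * o + a42 * i1 - (a21 + r1 + a24) * c2
           + beta_b * cs2 - ab_c * c2)
    do = (r1 * c2 - (r2 + a34) * o + beta_b * os - alpha_b * o)
    di1 = (a24 * c2 + a34 * o + a54 * i2 - (a42 + a45) * i1
           + beta_b * is1 - ab_c * i1)
    di2 = a45 * i1 - a54 * i2 + beta_b * is2 - ab_c * i2

    dcs1 = a21 * cs2 - a12 * cs1 - beta_b * cs1 + ab_c * c1
    dcs2 = (a12 * cs1 + r2 * os + a42 * is1 - (a21 + r1 + a24s) * cs2
            - beta_b * cs2 + ab_c * c2)
    dos = (r1 * cs2 - (r2 + a34s) * os - beta_b * os + alpha_b * o)
    dis1 = (a24s * cs2 + a34s * os + a54 * is2 - (a42 + a45) * is1
            - beta_b * is1 + ab_c * i1)
    dis2 = a45 * is1 - a54 * is2 - beta_b * is2 + ab_c * i2

    y[S_C1] = c1 + dt * dc1
    y[S_C2] = c2 + dt * dc2
    y[S_O] = o + dt * do
    y[S_I1] = i1 + dt * di1
    y[S_I2] = i2 + dt * di2
    y[S_CS1] = cs1 + dt * dcs1
    y[S_CS2] = cs2 + dt * dcs2
    y[S_OS] = os + dt * dos
    y[S_IS1] = is1 + dt * dis1
    y[S_IS2] = is2 + dt * dis2

    # renormalize occupancy (guards slow explicit-Euler drift)
    tot = (y[S_C1] + y[S_C2] + y[S_O] + y[S_I1] + y[S_I2]
           + y[S_CS1] + y[S_CS2] + y[S_OS] + y[S_IS1] + y[S_IS2])
    if tot > 0.0:
        inv = 1.0 / tot
        y[S_C1] *= inv
        y[S_C2] *= inv
        y[S_O] *= inv
        y[S_I1] *= inv
        y[S_I2] *= inv
        y[S_CS1] *= inv
        y[S_CS2] *= inv
        y[S_OS] *= inv
        y[S_IS1] *= inv
        y[S_IS2] *= inv


@njit(cache=True)
def _alpha_b(y, p):
    """Spark recruitment rate: LCC-triggered, SR-load sensitive."""
    csrb = y[S_CSRB]
    s = csrb * csrb / (csrb * csrb + p[P_KSR] * p[P_KSR])
    return p[P_ALPHA0] * y[S_O] * s


@njit(cache=True)
def _step_sparks(y, p, alpha_b, dt, stochastic, rs, rsi):
    """Advance the spark population; returns updated pb."""
    beta_b = p[P_BETAB]
    if stochastic:
        nbtot = int(p[P_NBTOT])
        nb = int(y[S_NB])
        # subdivide so binomial success probabilities stay well below 1
        nsub = 1
        pmax = alpha_b * dt if alpha_b > beta_b else beta_b * dt
        while pmax / nsub > 0.5:
            nsub *= 2
        h = dt / nsub
        for _ in range(nsub):
            dplus = _binomial(rs, rsi, nbtot - nb, alpha_b * h)
            dminus = _binomial(rs, rsi, nb, beta_b * h)
            nb += dplus - dminus
        y[S_NB] = float(nb)
        return nb / nbtot
    else:
        # exact exponential update of dpb/dt = alpha(1-pb) - beta*pb
        pb = y[S_NB]
        tot = alpha_b + beta_b
        if tot > 0.0:
            pinf = alpha_b / tot
            pb = pinf + (pb - pinf) * math.exp(-tot * dt)
        y[S_NB] = pb
        return pb


@njit(cache=True)
def _step_calcium(y, p, ical, inaca, pb, dt):
    """Advance the four Ca compartments (explicit Euler on the fluxes)."""
    cb = y[S_CB]
    ci = y[S_CI]
    csrb = y[S_CSRB]
    csri = y[S_CSRI]

    jrb = p[P_GB] * csrb * pb
    jca = -p[P_SCA] * ical
    jnaca = p[P_SNACA] * inaca
    jupb = p[P_VUP] * cb * cb / (cb * cb + p[P_KUP] * p[P_KUP])
    jupi = p[P_VUP] * ci * ci / (ci * ci + p[P_KUP] * p[P_KUP])
    jdc = (cb - ci) / p[P_TAUC]
    jdsr = (csrb - csri) / p[P_TAUSR]
    if p[P_GRI] > 0.0:
        r = p[P_CITH] / ci
        r2 = r * r
        jri = p[P_GRI] * csri / (1.0 + r2 * r2)
    else:
        jri = 0.0

    vb = p[P_VB]
    vi = p[P_VI]
    vsrb = p[P_VSRB]
    vsri = p[P_VSRI]
    bufc = p[P_BUFC]
    bufsr = p[P_BUFSR]

    y[S_CB] = cb + dt * bufc * (jrb + jca + jnaca - jupb - jdc)
    y[S_CI] = ci + dt * bufc * (jri + jdc * vb / vi - jupi)
    y[S_CSRB] = csrb + dt * bufsr * ((jupb - jrb) * vb / vsrb - jdsr)
    y[S_CSRI] = csri + dt * bufsr * (jupi * vi / vsri
                                     + jdsr * vsrb / vsri
                                     - jri * vi / vsri)


@njit(cache=True)
def _step_cell(y, p, dt, istim, stochastic, rs, rsi, ical_out):
    """One full update: gates -> LCC -> sparks -> Ca -> voltage/Na.

    Returns dV/dt (mV/ms) of this step for timestep adaptation.
    """
    iion = _currents(y, p, ical_out)
    ical = ical_out[0]
    inaca = ical_out[1]

    _step_gates(y, p, dt)
    ab = _alpha_b(y, p)
    _step_lcc(y, p, ab, p[P_BETAB], dt)
    pb = _step_sparks(y, p, ab, dt, stochastic, rs, rsi)
    _step_calcium(y, p, ical, inaca, pb, dt)

    dvdt = -(iion + istim)
    y[S_V] += dt * dvdt
    if p[P_NAI_CLAMPED] < 0.5:
        # Na bookkeeping: INa + 3 INaCa + 3 INaK (start-of-step values)
        y[S_NAI] += -dt * p[P_CONV_NA] * (ical_out[2]
                                          + 3.0 * inaca + 3.0 * ical_out[3])
    return dvdt


@njit(cache=True)
def run_paced_cell(y, p, cl, nbeats, stochastic, seed, cell_id,
                   rec_dt, t0, rec_v, rec_cb, rec_csrb, rec_pb):
    """Pace one cell for nbeats at cycle length cl, recording every rec_dt.

    Recording arrays must be length >= nbeats*cl/rec_dt + 1.  Returns the
    number of samples written.  t0 is the phase offset of the first
    stimulus (usually 0).
    """
    rs = np.empty(1, dtype=np.uint64)
    rs[0] = _stream_seed(seed, cell_id)
    ical_out = np.zeros(4)
    nbtot = p[P_NBTOT]

    tend = cl * nbeats
    t = 0.0
    nrec = 0
    next_rec = 0.0
    dt = p[P_DTMIN]
    dvdt = 0.0
    while t < tend - 1e-9:
        # record
        while next_rec <= t + 1e-9 and nrec < rec_v.shape[0]:
            rec_v[nrec] = y[S_V]
            rec_cb[nrec] = y[S_CB]
            rec_csrb[nrec] = y[S_CSRB]
            if stochastic:
                rec_pb[nrec] = y[S_NB] / nbtot
            else:
                rec_pb[nrec] = y[S_NB]
            nrec += 1
            next_rec += rec_dt
        # stimulus phase
        tb = (t - t0) % cl
        stim_on = (t >= t0) and (tb < p[P_STIM_DUR])
        if stim_on or abs(dvdt) > p[P_DVDT_SWITCH]:
            dt = p[P_DTMIN]
        else:
            dt = p[P_DTMAX]
        # do not step across a stimulus onset
        tnext_stim = t0 + math.ceil((t - t0 + 1e-9) / cl) * cl
        if t + dt > tnext_stim and t < tnext_stim:
            dt = tnext_stim - t
            if dt < 1e-9:
                dt = 1e-9
        istim = p[P_STIM_AMP] if stim_on else 0.0
        dvdt = _step_cell(y, p, dt, istim, stochastic, rs, 0, ical_out)
        t += dt
    return nrec


@njit(cache=True)
def relax_cell(y, p, duration):
    """Let the cell sit unstimulated (deterministic) for `duration` ms."""
    rs = np.zeros(1, dtype=np.uint64)
    ical_out = np.zeros(4)
    t = 0.0
    while t < duration:
        dt = p[P_DTMAX]
        dvdt = _step_cell(y, p, dt, 0.0, False, rs, 0, ical_out)
        if abs(dvdt) > p[P_DVDT_SWITCH]:
            dt = p[P_DTMIN]
        t += dt
    return y


@njit(cache=True)
def run_tissue(Y, p, nrow, ncol, dv, dx, stim_mask, stim_times,
               stochastic, seed, rec_dt, rec_cells, rec_traces,
               snap_dt, snapshots, tend, act_time, apd_map):
    """Monodomain tissue integration with Lie splitting.

    Y           : (ncells, NVAR) state array, row-major over (row, col)
    stim_mask   : (ncells,) 0/1 stimulated-region mask
    stim_times  : sorted array of stimulus onset times (ms)
    rec_cells   : indices of cells whose V is recorded every rec_dt
    rec_traces  : (len(rec_cells), nsamples) output
    snapshots   : (nframes, ncells) voltage field frames every snap_dt
                  (snap_dt <= 0 disables)
    act_time    : (nstim, ncells) first upstroke time per stimulus interval
                  (NaN if none); upstroke = upward crossing of -20 mV
    apd_map     : (nstim, ncells) APD at -40 mV for that activation (NaN
                  if unrepolarized or not activated)
    Returns (nrec, nsnap).
    """
    ncells = nrow * ncol
    rs = np.empty(ncells, dtype=np.uint64)
    for c in range(ncells):
        rs[c] = _stream_seed(seed, c)
    ical_out = np.zeros(4)

    dt_out = p[P_DTMAX]
    lap = np.zeros(ncells)
    dvdt = np.zeros(ncells)
    vprev = np.empty(ncells)
    for c in range(ncells):
        vprev[c] = Y[c, S_V]
    # per-cell activation bookkeeping
    act_t = np.full(ncells, -1.0)       # time of the pending upstroke
    act_beat = np.full(ncells, -1, dtype=np.int64)

    t = 0.0
    nrec = 0
    nsnap = 0
    next_rec = 0.0
    next_snap = 0.0
    nstim = stim_times.shape[0]
    istim_idx = 0
    while t < tend - 1e-9:
        while next_rec <= t + 1e-9 and nrec < rec_traces.shape[1]:
            for k in range(rec_cells.shape[0]):
                rec_traces[k, nrec] = Y[rec_cells[k], S_V]
            nrec += 1
            next_rec += rec_dt
        if snap_dt > 0.0:
            while next_snap <= t + 1e-9 and nsnap < snapshots.shape[0]:
                for c in range(ncells):
                    snapshots[nsnap, c] = Y[c, S_V]
                nsnap += 1
                next_snap += snap_dt

        # active stimulus?
        while istim_idx < nstim - 1 and t >= stim_times[istim_idx + 1] - 1e-9:
            istim_idx += 1
        stim_on = (nstim > 0 and t >= stim_times[istim_idx] - 1e-9
                   and t < stim_times[istim_idx] + p[P_STIM_DUR])

        # don't step across the next stimulus onset
        dt_step = dt_out
        if istim_idx + 1 < nstim:
            tn = stim_times[istim_idx + 1]
            if t < tn and t + dt_step > tn:
                dt_step = tn - t
        elif nstim > 0 and t < stim_times[istim_idx]:
            tn = stim_times[istim_idx]
            if t + dt_step > tn:
                dt_step = tn - t

        # --- reaction substep (adaptive subcycling per cell) ---
        for c in range(ncells):
            istim = 0.0
            if stim_on and stim_mask[c] > 0:
                istim = p[P_STIM_AMP]
            yc = Y[c]
            if istim != 0.0 or abs(dvdt[c]) > p[P_DVDT_SWITCH]:
                nsub = int(dt_step / p[P_DTMIN] + 0.5)
                if nsub < 1:
                    nsub = 1
                h = dt_step / nsub
                for _ in range(nsub):
                    dvdt[c] = _step_cell(yc, p, h, istim, stochastic,
                                         rs, c, ical_out)
            else:
                dvdt[c] = _step_cell(yc, p, dt_step, istim, stochastic,
                                     rs, c, ical_out)

        # --- diffusion substep (explicit 5-point, no-flux boundaries) ---
        if dv > 0.0:
            rr = dv * dt_step / (dx * dx)
            for i in range(nrow):
                for jj in range(ncol):
                    c = i * ncol + jj
                    vc = Y[c, S_V]
                    up = Y[(i - 1) * ncol + jj, S_V] if i > 0 else vc
                    dn = Y[(i + 1) * ncol + jj, S_V] if i < nrow - 1 else vc
                    lf = Y[i * ncol + jj - 1, S_V] if jj > 0 else vc
                    rt = Y[i * ncol + jj + 1, S_V] if jj < ncol - 1 else vc
                    lap[c] = up + dn + lf + rt - 4.0 * vc
            for c in range(ncells):
                Y[c, S_V] += rr * lap[c]

        t += dt_step
        # --- activation / repolarization bookkeeping ---
        for c in range(ncells):
            vnew = Y[c, S_V]
            if vprev[c] < -20.0 and vnew >= -20.0:
                if act_beat[c] < istim_idx:  # first upstroke this interval
                    act_beat[c] = istim_idx
                    act_t[c] = t
                    if istim_idx < act_time.shape[0]:
                        act_time[istim_idx, c] = t
            elif vprev[c] >= -40.0 and vnew < -40.0 and act_t[c] >= 0.0:
                b = act_beat[c]
                if 0 <= b < apd_map.shape[0] and math.isnan(apd_map[b, c]):
                    apd_map[b, c] = t - act_t[c]
                act_t[c] = -1.0
            vprev[c] = vnew
    return nrec, nsnap
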