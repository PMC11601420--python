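"""Four-compartment phenomenological Ca cycling.

The cell is partitioned into cytosolic and sarcoplasmic-reticulum (SR)
volumes near junctional (J) and non-junctional (NJ) RyR clusters, with
average free concentrations cb, ci (cytosol) and csrb, csri (SR).  The
compartments exchange Ca through release, SERCA uptake and linear
diffusive fluxes; the L-type current and the Na/Ca exchanger connect the
J cytosolic space to the exterior.

Sign conventions (tested): release moves SR -> cytosol, uptake moves
cytosol -> SR, and the diffusive fluxes are positive from the J side to
the NJ side.  All fluxes are in uM/ms referred to the J cytosolic volume
``vb``; explicit volume ratios appear at the update site.
"""

from __future__ import annotations

import dataclasses

__all__ = ["CaState", "CaGeometry", "CaFluxes", "CaParams",
           "release_flux_junctional", "compute_all_fluxes", "step_calcium",
           "buffered_total"]


@dataclasses.dataclass
class CaState:
    cb: float      # uM, cytosol near J clusters
    ci: float      # uM, cytosol near NJ clusters
    csrb: float    # uM, SR near J clusters
    csri: float    # uM, SR near NJ clusters

    def __post_init__(self):
        if min(self.cb, self.ci, self.csrb, self.csri) <= 0:
            raise ValueError("concentrations must be positive")


@dataclasses.dataclass
class CaGeometry:
    """Relative compartment volumes (J cytosol = 1 by convention)."""

    vb: float = 1.0
    vi: float = 9.0
    vsrb: float = 0.35
    vsri: float = 3.15

    def __post_init__(self):
        if min(self.vb, self.vi, self.vsrb, self.vsri) <= 0:
            raise ValueError("volumes must be positive")


@dataclasses.dataclass
class CaFluxes:
    """The eight fluxes of the compartment model (uM/ms, vb-referred)."""

    jrb: float     # RyR release from J clusters
    jri: float     # RyR release from NJ clusters (default disabled)
    jupb: float    # uptake, J cytosol -> SR
    jupi: float    # uptake, NJ cytosol -> SR (vi-referred)
    jdsr: float    # SR diffusive exchange, J -> NJ (vsrb-referred)
    jdc: float     # cytosolic diffusive exchange, J -> NJ
    jca: float     # LCC flux into the J cytosol
    jnaca: float   # exchanger flux into the J cytosol (signed)


@dataclasses.dataclass
class CaParams:
    gb: float = 0.11428571   # 1/ms, effective RyR cluster conductance
    vup: float = 0.4         # uM/ms, SERCA maximum rate
    kup: float = 0.5         # uM, SERCA half-saturation
    tauc: float = 5.0        # ms, cytosolic exchange time constant
    tausr: float = 50.0      # ms, SR exchange time constant
    bufc: float = 0.1        # instantaneous cytosolic buffering factor
    bufsr: float = 1.0       # SR buffering factor
    gri: float = 0.0         # NJ release conductance (0: disabled)
    cith: float = 1.0        # uM, NJ release activation threshold

    def __post_init__(self):
        if min(self.gb, self.vup, self.kup, self.tauc, self.tausr,
               self.bufc, self.bufsr) <= 0:
            raise ValueError("parameters must be positive")


def release_flux_junctional(csrb: float, pb: float, gb: float) -> float:
    """Junctional RyR release flux gb * csrb * pb (uM/ms)."""
    if not 0.0 <= pb <= 1.0:
        raise ValueError("pb must lie in [0, 1]")
    if csrb <= 0:
        raise ValueError("csrb must be positive")
    if gb < 0:
        raise ValueError("gb must be nonnegative")
    return gb * csrb * pb


def compute_all_fluxes(ca: CaState, pb: float, lcc_flux: float,
                       naca_flux: float, params: CaParams) -> CaFluxes:
    """Populate the eight compartment fluxes at the present state.

    ``lcc_flux`` and ``naca_flux`` are membrane fluxes into the J cytosol
    (already converted from current densities).  NJ release ``jri`` uses a
    threshold activation on the local cytosolic Ca and is disabled by
    default (gri = 0), reflecting spark recruitment being a junctional
    phenomenon in the ventricular geometry.
    """
    jrb = release_flux_junctional(ca.csrb, pb, params.gb)
    c2 = ca.cb * ca.cb
    jupb = params.vup * c2 / (c2 + params.kup * params.kup)
    ci2 = ca.ci * ca.ci
    jupi = params.vup * ci2 / (ci2 + params.kup * params.kup)
    jdc = (ca.cb - ca.ci) / params.tauc
    jdsr = (ca.csrb - ca.csri) / params.tausr
    if params.gri > 0.0:
        r = params.cith / ca.ci
        r2 = r * r
        jri = params.gri * ca.csri / (1.0 + r2 * r2)
    else:
        jri = 0.0
    return CaFluxes(jrb=jrb, jri=jri, jupb=jupb, jupi=jupi,
                    jdsr=jdsr, jdc=jdc, jca=lcc_flux, jnaca=naca_flux)


def step_calcium(ca: CaState, fluxes: CaFluxes, geom: CaGeometry,
                 params: CaParams, dt: float) -> CaState:
    """Explicit Euler update of the four compartments."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = fluxes
    cb = ca.cb + dt * params.bufc * (f.jrb + f.jca + f.jnaca
                                     - f.jupb - f.jdc)
    ci = ca.ci + dt * params.bufc * (f.jri + f.jdc * geom.vb / geom.vi
                                     - f.jupi)
    csrb = ca.csrb + dt * params.bufsr * ((f.jupb - f.jrb)
                                          * geom.vb / geom.vsrb - f.jdsr)
    csri = ca.csri + dt * params.bufsr * (f.jupi * geom.vi / geom.vsri
                                          + f.jdsr * geom.vsrb / geom.vsri
                                          - f.jri * geom.vi / geom.vsri)
    if min(cb, ci, csrb, csri) <= 0:
        raise ArithmeticError(
            "nonpositive concentration after step; timestep or parameters "
            "inconsistent")
    return CaState(cb=cb, ci=ci, csrb=csrb, csri=csri)


def buffered_total(ca: CaState, geom: CaGeometry, params: CaParams) -> float:
    """Conserved total Ca of a closed cell: sum of v * c / buffer factor."""
    return (geom.vb * ca.cb / params.bufc
            + geom.vi * ca.ci / params.bufc
            + geom.vsrb * ca.csrb / params.bufsr
            + geom.vsri * ca.csri / params.bufsr)
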