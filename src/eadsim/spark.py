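"""Stochastic birth-death dynamics of the Ca-spark population.

Junctional ryanodine-receptor clusters ignite sparks at a recruitment rate
``alpha_b`` per quiescent cluster and extinguish at ``beta_b`` per active
cluster.  Over a step dt the number of active clusters ``nb`` (out of
``Nb`` total) changes by the difference of two binomial draws,

    nb' = nb + Binomial(Nb - nb, alpha_b dt) - Binomial(nb, beta_b dt),

so 0 <= nb' <= Nb by construction.  The mean-field (Nb -> infinity) limit
is the ODE dpb/dt = alpha_b (1 - pb) - beta_b pb for the spark fraction
pb = nb/Nb.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import _kernel as K

__all__ = ["SparkState", "SparkRates", "step_spark_counts_stochastic",
           "step_spark_fraction_deterministic", "spark_recruitment_rate",
           "RecruitmentParams"]


@dataclasses.dataclass
class SparkState:
    """Spark bookkeeping for one cell."""

    nb: int          # active junctional clusters
    Nb: int          # total junctional clusters

    def __post_init__(self):
        if self.Nb <= 0:
            raise ValueError("Nb must be positive")
        if not 0 <= self.nb <= self.Nb:
            raise ValueError("nb must lie in [0, Nb]")

    @property
    def pb(self) -> float:
        """Spark fraction nb/Nb."""
        return self.nb / self.Nb


@dataclasses.dataclass
class SparkRates:
    """Recruitment and extinction rates (1/ms)."""

    alpha_b: float
    beta_b: float

    def __post_init__(self):
        if self.alpha_b < 0:
            raise ValueError("alpha_b must be nonnegative")
        if self.beta_b <= 0:
            raise ValueError("beta_b must be positive")


@dataclasses.dataclass
class RecruitmentParams:
    """Parameters of the recruitment-rate law alpha0 * f_open * S(csrb)."""

    alpha0: float = 0.35     # 1/ms, overall recruitment scale
    ksr: float = 500.0       # uM, SR-load half-saturation


def step_spark_counts_stochastic(state: SparkState, rates: SparkRates,
                                 dt: float, rng: np.random.Generator
                                 ) -> SparkState:
    """One binomial birth-death step of the spark count.

    ``rng`` is a numpy Generator; the heavy-duty simulation kernel uses an
    equivalent per-cell counter-based stream instead (see
    :mod:`eadsim._kernel`), and the two are cross-checked in the tests.
    If a rate times dt exceeds 1 the step is subdivided internally so the
    binomial success probabilities stay valid.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pmax = max(rates.alpha_b, rates.beta_b) * dt
    nsub = 1
    while pmax / nsub > 1.0:
        nsub *= 2
    h = dt / nsub
    nb = state.nb
    for _ in range(nsub):
        dplus = rng.binomial(state.Nb - nb, min(rates.alpha_b * h, 1.0))
        dminus = rng.binomial(nb, min(rates.beta_b * h, 1.0))
        nb = nb + dplus - dminus
    return SparkState(nb=int(nb), Nb=state.Nb)


def step_spark_fraction_deterministic(pb: float, rates: SparkRates,
                                      dt: float) -> float:
    """Exact one-step update of the mean-field spark fraction ODE."""
    if not 0.0 <= pb <= 1.0:
        raise ValueError("pb must lie in [0, 1]")
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    tot = rates.alpha_b + rates.beta_b
    if tot == 0.0:
        return pb
    pinf = rates.alpha_b / tot
    return pinf + (pb - pinf) * math.exp(-tot * dt)


def spark_recruitment_rate(lcc_open_fraction: float, csrb: float,
                           params: RecruitmentParams | None = None) -> float:
    """Spark recruitment rate: LCC-triggered and SR-load sensitive.

    alpha_b = alpha0 * f_open * csrb^2 / (csrb^2 + Ksr^2).  Zero when no
    L-type channels are open; monotone increasing in SR load.
    """
    if lcc_open_fraction < 0 or csrb < 0:
        raise ValueError("inputs must be nonnegative")
    if params is None:
        params = RecruitmentParams()
    s = csrb * csrb / (csrb * csrb + params.ksr * params.ksr)
    return params.alpha0 * lcc_open_fraction * s


def kernel_binomial(seed: int, cell_id: int, n: int, p: float,
                    ndraws: int) -> np.ndarray:
    """Draws from the kernel's counter-based binomial sampler (testing aid)."""
    rs = np.array([K._stream_seed(seed, cell_id)], dtype=np.uint64)
    return np.array([K._binomial(rs, 0, n, p) for _ in range(ndraws)])
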