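# Model and methods

## Scope

`eadsim` simulates a paced ventricular myocyte in which the only noise
source is the stochastic recruitment and extinction of Ca sparks, couples
lattices of such cells into monodomain tissue, and analyzes the resulting
APD dynamics through a one-dimensional restitution map.  The intended use
is the study of early afterdepolarizations (EADs) produced by reduced
Ca-induced inactivation of the L-type Ca current, and of how electrotonic
coupling converts cellular EAD variability into tissue-level EAD
alternans, conduction block and wave break.

## Spark population

Junctional RyR clusters are treated as a population of `Nb` identical
binary units.  Over a step `dt` the active count `nb` gains
`Binomial(Nb − nb, αb·dt)` and loses `Binomial(nb, βb·dt)` clusters;
probabilities above 1/2 trigger internal step subdivision so the
binomial parameters stay valid (preserving the mean rates rather than
clamping).  The recruitment rate is

    αb = α0 · f_open · csrb² / (csrb² + Ksr²),

proportional to the spark-off L-type open fraction (sparks are triggered
by LCC openings) and saturating in SR load; extinction is a constant
`βb = 1/30 ms⁻¹` (a ~30 ms spark lifetime).  The mean-field limit
`dpb/dt = αb(1 − pb) − βb·pb` is integrated exactly
(exponential update) and is the "deterministic" model variant.

Release flux is `Jrb = gb·csrb·pb`.  The pair `(α0, gb)` controls the
*quantization* of release at fixed mean flux: fewer, larger sparks give
proportionally larger relative noise (σ ∝ 1/√n_active).  The calibrated
values (α0 = 0.35 ms⁻¹, gb = 0.114 ms⁻¹) set the peak active fraction to
a few percent of `Nb = 4000`, which reproduces the observed APD90
coefficient of variation (~2.3–2.8 %) without altering the mean-field
dynamics.

Each cell owns a counter-based RNG stream (splitmix64 state keyed by the
global seed and the cell index) with an exact inverse-CDF binomial
sampler, so tissue runs are bitwise reproducible and independent of grid
traversal order; with `DV = 0` every lattice cell reproduces the
isolated-cell trajectory of the matching stream exactly.

## Calcium compartments

Four well-mixed pools: cytosol and SR near junctional (cb, csrb) and
non-junctional (ci, csri) clusters, with relative volumes
vb : vi : vsrb : vsri = 1 : 9 : 0.35 : 3.15.  Uptake is a Hill-2 SERCA
flux (`vup = 0.4 µM/ms`, `Kup = 0.5 µM`); the compartment pairs exchange
by linear relaxation (τc = 5 ms cytosol, τsr = 50 ms SR); buffering is an
instantaneous multiplicative factor (0.1 cytosolic, 1.0 SR).
Non-junctional release exists behind a config flag (threshold activation
in local ci) but is **off** by default: in the ventricular geometry
t-tubules distribute junctional clusters through the cell interior, and
release is junctional.  With membrane fluxes off, the model conserves
Σ v·c/β to float precision (tested at 10⁻⁶ relative over 10⁴ steps).
Sign conventions — release SR→cytosol, uptake cytosol→SR, diffusive
fluxes positive junctional→non-junctional — are fixed and tested.

## L-type Ca current

Ten Markov states: a spark-off group (C1, C2, O, I1, I2) facing bulk
junctional Ca and a mirrored spark-on group facing spark-domain Ca.
Activation C1↔C2 follows the classic L-type d-gate steady state and time
constant; opening C2↔O is fast (r1 = 0.3, r2 = 3 ms⁻¹).  Ca-induced
inactivation enters through

    a24 = a24o + ACa·FCa(cb),  a34 = a34o + ACa·FCa(cb),
    FCa = 1 / (1 + (cth/cb)²),

with small voltage-independent baselines (0.002 ms⁻¹) so that the ACa
term dominates.  `cth = 0.3 µM` sits well below systolic junctional Ca:
during the plateau FCa is nearly saturated and the inactivation rate is
essentially `ACa` itself, which makes the normal (0.15 ms⁻¹) versus
reduced (0.09 ms⁻¹) comparison a clean ~40 % change in inactivation
rather than an indirect Ca-feedback effect.  Spark-on channels see
spark-domain Ca far above threshold and use FCa = 1 exactly.  Recovery
I1→C2 has a small voltage-independent floor (3.65×10⁻³ ms⁻¹) plus a
component switched on below ≈ −30 mV; a slow deep state I2 (entry
4×10⁻³ ms⁻¹, exit gated below ≈ −55 mV at 4.65×10⁻³ ms⁻¹) carries the
diastolic-interval memory that shapes restitution.  Both groups exchange
at the spark rates (αb forward, βb backward) for all corresponding
states; a config flag restricts migration to O↔OS only.  Occupancies are
advanced explicitly and renormalized each step (probability conserved to
10⁻⁶ over 10⁵ steps).  The current uses the constant-field (GHK) driving
force times the total open fraction O + OS.

## Membrane currents and cell assembly

INa uses the classic fast-Na gates (m³hj); IKr, IKs, IK1, Ito (fast and
slow), INaK and INaCa follow rabbit-ventricular formulations with
conductances treated as calibration parameters.  The IKs deactivation
memory (two activation gates, the slow one 4× slower) provides
rate-dependent repolarization reserve; INaCa, driven by junctional Ca,
is the main route by which spark noise reaches the voltage.  The update
order per step is fixed: HH gates → LCC occupancies → spark population →
Ca compartments → voltage and Na (dV/dt = −Iion/Cm, Cm = 1 µF/cm²).
Gates advance by Rush–Larsen (exact for frozen V); the timestep is
adaptive between 0.01 and 0.1 ms, refining whenever |dV/dt| > 1 mV/ms or
a stimulus is active, and never stepping across a stimulus onset.
Default stimulus: −80 µA/µF for 1 ms.

Intracellular Na is **clamped** at 12 mM by default.  Dynamic Na (flag
`nai_clamped: 0`) drifts on a many-hundred-beat timescale under the
pacing protocols used here, which makes long fixed-CL statistics
non-stationary; clamping makes every reported quantity a property of a
well-defined periodic regime.  Ki is fixed at 140 mM.

## Calibration

The phenomenological constants are not taken from any published table;
they were fixed, once, by a coordinate search against four anchors:
(i) steady-state APD90 mean ≈ 237 ms and σ ≈ 6.3 ms (cv ≈ 2.7 %) at
CL = 500 ms with Nb = 4000 under normal inactivation; (ii) no EAD
notches at ACa = 0.15 anywhere in a 440–552 ms dynamic sweep;
(iii) first EAD-positive cycle length ≈ 500 ms at ACa = 0.09; (iv) an
S1S2 restitution curve that is gradual at short DI and rises abruptly
near DI ≈ 350 ms.  The shipped `paramsets/default.yaml` (ACa = 0.15) and
`paramsets/ead.yaml` (identical except ACa = 0.09) are the result.  The
generic `calibrate()` routine (coordinate descent over multiplicative
moves, deterministic per seed) is part of the public API and is
exercised in the tests at toy scale.

Measured at the calibrated point (seeds 11/23/37, 340 steady beats):
mean APD90 229.2–229.5 ms, σ 5.6–6.5 ms, cv 2.4–2.8 %, no EAD notches at
ACa = 0.15; deterministic dynamic sweep onset at ACa = 0.09: 480 ms,
with APD alternans (≈ 260/160 ms, EADs on the long beats) from onset
through 560 ms.

## Tissue solver

First-order Lie splitting: a reaction substep (each cell advanced by the
single-cell scheme, with per-cell subcycling to 0.01 ms during upstrokes)
followed by an explicit 5-point-Laplacian diffusion substep with
no-flux (ghost-mirror) boundaries.  `DV = 10⁻⁴ cm²/ms`, `Δx = 0.015 cm`;
the diffusion step 0.1 ms is far below the dx²/(4DV) = 0.56 ms stability
bound, and the solver refuses unstable requests.  The kernel tracks, per
stimulus interval and per cell, the first upstroke time (upward −20 mV
crossing) and the APD at −40 mV, which yields activation and APD maps
without storing full per-cell traces.  Conduction velocity at the
default parameters is ≈ 11 cm/s; plane-wave speed increases with DV
(tested at three values).

## Measurement conventions

Upstroke: upward crossing of −20 mV within 10 ms of a stimulus (robust
to EAD plateau oscillations, which must not count as new beats).  APD:
from upstroke to the interpolated downward crossing of −40 mV
(`fixed_mv`) or of the per-beat 90 %-repolarization level
(`percent_repol`).  Beats that never repolarize before the next stimulus
are censored: flagged, set to the full interval, excluded from mean/σ
but counted.  σ is the population standard deviation.  EAD detector: a
local maximum above −40 mV after the primary peak with prominence
≥ 2 mV.  DI is the time from the −40 mV crossing to the next upstroke.
S1S2 trials restart from the stored S1 steady state, so they are
independent; in the tissue variant the DI of a conducted S2 beat is
measured at the distal cell (wavefront arrival minus local
repolarization).

## Restitution map

`F` is an interpolating *natural* cubic spline through measured (DI,
APD) points — the measured points are trusted, not smoothed (a smoothing
option exists for noisy tissue data).  Outside the sampled DI range `F`
is clamped to its endpoint values: extrapolated physiology would
manufacture spurious fixed points.  Iteration: `A⁺ = F(DI)`,
`DI⁺ = T − A⁺`; a trajectory terminates as conduction block when DI
falls below the block threshold (25 ms for tissue-derived maps, 0
otherwise; block is terminal, not restarted).  Period classification
compares the final iterates at 10⁻³ ms.  Second-iterate fixed points are
bracketed on a 2000-point grid and bisected to 10⁻⁶ ms; stability is
|dG²/dDI| < 1 with the chain rule on the spline derivative (zero in the
clamped region).  The onset scan `period1_stability_loss` reports the
first period at which no stable period-1 root remains.

## Synthetic-data generators

`fixtures.py` produces (i) trapezoid action potentials whose threshold
crossings have closed-form times (measurement oracles), (ii) toy
restitution point sets — a shallow monotone curve (slope < 1 everywhere,
supercritical contrast case) and a sigmoid-step curve mimicking the
abrupt EAD rise, and (iii) reverse-engineered spline maps with an exact
planted period-2 orbit (F(di_a) = T − di_b and vice versa).  These share
no code with the analysis paths they test.  They emulate waveform
geometry and map topology only — not ionic dynamics — so passing those
tests validates the measurement and map machinery, not the cell model.

## Problem sizes

Simulations in the test suite and acceptance script run at sizes chosen
to keep a full run on one CPU within minutes while leaving the measured
statistics well-resolved: 1550–2050 beats for the CL = 500 stochastic
statistics (σ estimates resolved to ~±4 %), 200 beats per CL (last 50
scored) for dynamic sweeps, 250 beats for the tissue noise-damping
curve at N ∈ {1, 5, 10}, a 60 × 3 strip with 5-ms S2 resolution for the
block threshold, and a 30 × 30 sheet for the rate-switch (420 → 530 ms)
EAD-alternans run.  Larger, paper-scale variants of the same protocols
are available through the CLI presets with `--full`.

## Known limitations

- The EAD step of the reconstructed S1S2 curve raises APD by ~60–110 ms
  (upper branch ≈ 260–295 ms).  Reference analyses of this transition
  place the upper branch near 450 ms; the smaller amplitude here shifts
  the map's period-doubling onset to T ≈ 528 ms (reference ≈ 650 ms),
  raises the strip conduction-block threshold to distal DI ≈ 50–55 ms
  (reference ≈ 25 ms), and keeps the short-beat DI during CL = 530
  alternans (~270 ms) far above the refractory floor, so paced 2D tissue
  shows EAD alternans with waveback heterogeneity but does not proceed
  to conduction block and reentry.  Attempts to enlarge the EAD
  amplitude destabilized the normal-inactivation cell (spurious notches)
  or broke the APD-variability calibration, and were rejected; the
  discrepancies are reported as-is by the acceptance tests.
- The stochastic normal cell crosses the 2-mV notch threshold on ~0.5 %
  of beats (ripples of 2–3 mV, far below genuine 15–45 mV EADs); the
  deterministic normal cell never does.
- Single-channel LCC gating, Ca waves, 3D tissue, heterogeneous or
  anisotropic conductivity and β-adrenergic modulation are out of scope.
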