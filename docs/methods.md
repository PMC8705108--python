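# Methods

This note documents the model solved by `crossflow`, its assumptions, the
numerical choices, and the limits of what the test suite demonstrates.

## Physical model and assumptions

The package computes the steady state of inside-out cross-flow
ultrafiltration of a dispersion of mono-disperse Brownian hard spheres in a
thin channel (cylindrical CM, double-flat-sheet FMM, or flat-sheet-over-
substrate FMS).  The governing equations are the effective Stokes equation
with concentration-dependent viscosity, incompressibility, and the
advection–diffusion equation for the particle volume fraction, closed by
the Darcy–Starling boundary condition for the permeate flux,
vw = Lp(ΔTP − Π(φw)).  Assumptions:

* **Near-equilibrium dispersion.**  The single-particle shear Péclet number
  Pea = γ̇a²/D0 is small, so equilibrium forms of Π, D and η apply.  The
  constitutive set — Carnahan–Starling osmotic pressure, short-time
  gradient diffusion D = D0·Ksed/S, two-part viscosity η∞ + Δη — is
  accurate for fluid-state hard spheres up to the freezing transition
  φf = 0.494.  Above φf the code refuses to evaluate (cake formation is not
  modelled).
* **Thin channel, developed CP layer.**  R/L ≪ 1 and the boundary-layer
  smallness parameter is εδ = 1/PeR with PeR = R·Lp·⟨ΔT(l)P⟩/D0.  The
  solution is a leading-order matched asymptotic expansion in εδ;
  longitudinal diffusion, O(εδ²), is neglected in the particle flux.
* **Fully retentive membrane, laminar flow, no fouling.**  Validity flags
  for all of these (Table of conditions: Pea ≤ 0.1, R/L ≤ 0.01, Re ≤ 2000,
  Re·R/L < 0.1, φb·PeR < 1, β ≥ εδ) are computed with every indicator
  report; they warn rather than abort.

### Outer (bulk) solution

The axial pressure solves the exact linear two-point problem
P″ = (K/L)²(P − Pperm − Π(φw(z))) with P(L) = PL and the inlet slope fixed
by the centerline velocity, u0 = −RH²/(λ1ηs)·dP/dz.  The printed-form
integral representation of this solution is typographically ambiguous in
the source material, so the ODE is solved directly: cosh/sinh homogeneous
solutions plus a variation-of-parameters particular integral, whose two
cumulative quadratures are evaluated with composite Simpson on the axial
grid.  Consequences, enforced by tests: the homogeneous (φb = 0) limit
matches the closed form to 1e-10; u0(z) is an analytic derivative, so
du0/dz = −(λ2/RH)vw and volume conservation Q0 = QL + Qperm hold to
quadrature precision (≈1e-12 relative).

The operating input is the channel-length-averaged linearized TMP
⟨ΔT(l)P⟩ (the impermeable-channel pressure profile average minus Pperm);
Pperm is recovered from it by inverting the linear bookkeeping.  PeR is
defined with this constant, so it is a single number per run; in the film
exponent the combination is independent of that choice because the
Lp·⟨ΔT(l)P⟩ factor cancels.

### Inner (CP-layer) solution and matching

With the film exponent E(y,z) = vw(z)∫_y^R dy′/D(φ), the matched
concentration is φ = (φw−φb)e^{−E} + φb(1 − E·e^{−E}) and the axial
velocity is u = u0(z)·U(y,z) with
U = (1 + y/R)·∫_y^R η⁻¹dy′ / ∫_0^R η⁻¹dy′ (parabola for constant η).  The
transversal velocity is v = vw(z)·Vout(y) with the kind-specific cubic
Vout.  For FMM the layer is solved on [0, R] and mirrored; for FMS the
single layer sits at the top wall and the substrate side is bulk.  The
wall shear stress never appears explicitly — the normalization of U
absorbs it.

Because φ depends on y only through E, the layer is parametrized by E
itself: y(E) = R − (1/vw)∫_0^E D(φ(E′))dE′ — the film ODE dE/dy = −vw/D in
inverse form.  All cross-sectional averages (particle flux φ·u, velocity,
concentration, and the Newton sensitivity below) become cumulative
trapezoid sums over a fixed E grid, vectorized over all axial nodes, with
a linear-interpolation partial-cell correction where the layer reaches the
channel centerline (low PeR).  Beyond the grid end (E = 40) the matched
field is bulk to ~2e-16 and the remaining cross-section integral is a
cubic polynomial, integrated exactly by 5-node composite Simpson.

### Wall-concentration fixed point

φw(z) is determined by cross-sectional particle-flux conservation
J̄z(z) = J̄z(0).  The inlet wall value is pinned to the feed concentration
(no CP layer has developed at z = 0) and the conserved reference is the
solution's own inlet flux, which equals the nominal φb·ū0 up to the
O(εδ) matching correction of the concentration ansatz (≈0.25% at
PeR = 78).  The update is a damped Newton step on the layer amplitude:

    (φw − φb) += ω · (J̄z0 − J̄z) / S,   S = cross average of e^{−E}·u,

where S is the exact sensitivity of J̄z to the amplitude (which multiplies
e^{−E} in the matched field).  ω = 0.5, halved whenever the sup-norm
residual increases; convergence is declared at max_z|J̄z/J̄z0 − 1| ≤ 1e-6.
Two safeguards act only away from the fixed point: a per-step growth cap
max(3Δ, 10φb) on the amplitude, and a ceiling keeping Π(φw) ≤ 0.99 of the
local transmembrane pressure of the previous iterate (without it, early
iterates at strong-permeation conditions transiently exhaust the axial
flow before the osmotic back-pressure has built up).  Typical runs
converge in 25–40 iterations, ≈0.2 s on one CPU at the default grids.

Failure modes are reported as distinct exceptions (and CLI exit codes):
freezing/cake formation when φw reaches φf (for 10 nm particles this
happens for TMP ≳ 7 kPa), axial flow exhaustion when u0(z) → 0, permeate
reversal when the TMP cannot stay positive along the whole channel
(detected up front when PL ≤ Pperm), and non-convergence.

## Parameters that matter

| Parameter | Default | Why |
|---|---|---|
| T, ηs | 293.15 K, 1.0e-3 Pa·s | water at room temperature; gives D0(3.13 nm) = 6.86e-11 m²/s and PeR = 78 for the reference scenario |
| kB | 1.380649e-23 J/K | SI definition |
| φf | 0.494 | hard-sphere freezing transition; domain guard of all correlations |
| PL | 101325 Pa | outlet at atmospheric pressure |
| W | 1 m | flat-sheet width; all per-channel indicators are W-independent (tested) |
| ρ (Reynolds) | 1000 kg/m³ | dilute aqueous feed; used only in validity flags |
| n_z | 129 | uniform axial nodes (odd, Simpson-compatible) |
| E grid | 321 nodes on [0, 8] + 80 on [8, 40] | dense where φ varies (decay scale E ~ 1) |
| tol, max_iter | 1e-6, 500 | sup-norm flux residual |

Problem sizes were chosen so a full solve is a fraction of a second and
the entire benchmark sweep suite runs in a couple of minutes; a
grid-doubling test bounds the discretization sensitivity of β well below
the model's O(εδ) accuracy.

## Scenario fixtures

The builtin scenarios encode one reference membrane (R = 0.5 mm,
L = 0.5 m, Lp = 6.7e-10 m/(Pa·s), κ = 1.36e-16 m² where thickness is
given) with two particle sizes (a = 3.13 nm at TMP = 16 kPa,
ū0 = 3.40e-2 m/s; a = 10 nm at TMP = 5 kPa, ū0 = 1.11e-2 m/s, both at
PeR ≈ 78), shear-matched FMM variants, and the master-curve families
(CM/FMM/FMS-1..4, G1/G2) that hold the universality duplet
(β0/PeR, γ0/PeR) fixed while varying R, membrane thickness, feed
concentration and inlet velocity.  PeR sweeps vary the TMP at fixed
everything else, which is exact because PeR is linear in TMP.  Table-row
scenarios default to TMP = 16 kPa; the collapse driver retargets TMP per
requested PeR.

## Design choices where the design was open

* **Cup-mixing outlet concentration.**  The identity α = 1/(1−β) refers to
  the concentration of the dispersion collected at the outlet port, i.e.
  the flux-weighted (cup-mixing) average J̄z(L)/ū(L) with ū the outer
  volumetric average — not the plain area average of φ(y,L), which weights
  the stagnant enriched wall layer and is several times larger.  Both are
  exposed; the consistency test uses the cup-mixing value (agreement
  within 1%).
* **Inlet normalization.**  Pinning φw(0) = φb and conserving the
  solution's own inlet flux keeps the wall profile starting at the feed
  value, as physical intuition (zero entrance length for the layer)
  demands; the alternative — conserving φb·ū0 exactly — forces
  φw(0) ≈ 3φb to offset the matching-correction dip and was rejected.
* **K/K\* bookkeeping.**  The reported scaling ratio is
  K²/(ηsLpL²/R³) = λ1λ2(R/RH)³ = {16, 3, 3/2}; the K values themselves are
  the physically meaningful check.

## What the universality tests do and do not show

The three-variable description β ≈ F(PeR, β0/PeR, γ0/PeR) is exact in the
van't Hoff / constant-transport limit, and the test suite confirms the
implementation collapses parameter families to a fraction of a percent in
that limit.  With
the full Carnahan–Starling thermodynamics two departures appear and are
quantified by the acceptance suite rather than hidden:

1. Families reaching a given PeR at very different absolute TMP (rows with
   small Lp need proportionally larger TMP) operate at different wall
   concentrations, and the osmotic nonlinearity Z(φw) breaks the strict
   collapse: a few percent at PeR ≈ 40–80, growing to ~20% at PeR = 150
   for rows whose TMP differs by 2.5×.
2. The three variables are built from the *linearized* TMP; rows with
   large effective permeability (K up to 0.59 when R is halved) carry an
   O(K²) actual-vs-linearized pressure correction of several percent, and
   at low PeR such rows may admit no valid solution at all (the TMP falls
   below half the axial pressure drop and the permeate reverses).

Within the 1–20 kPa operating window of the benchmark scenarios, families
sharing the pressure scale trace one master curve to plot accuracy
(cross-geometry spread 1.6–2.6%).

## Known limitations

* Generic CP-layer physics only: no cake/fouling layer, no pore clogging,
  no partially retentive membranes, no polydispersity, no charged-particle
  interactions (the hard-sphere correlations underestimate, e.g., BSA
  osmotic pressure at off-isoelectric pH).
* Steady state only; startup transients are out of scope.
* The matched solution is leading-order in 1/PeR: quantities carry O(εδ)
  (≈1%) method error at PeR = 78, which is why several conservation
  cross-checks are asserted at the percent rather than machine level.
* Spacer-filled channels, spiral-wound modules and structured membranes
  are not modelled.
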