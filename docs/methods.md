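# Methods

## Problem

Endovascular coiling treats an intracranial aneurysm by packing its sac with
platinum wire so that blood largely stops circulating inside it.  Whether the
treatment "works" hemodynamically is usually judged by wall shear stress
(WSS) and the oscillatory shear index (OSI) on the aneurysm wall, and both
depend on blood rheology — in particular on the hematocrit, which differs
systematically between patients.  `coilflow` models a bilobed (double-dome)
aneurysm on a straight parent vessel under pulsatile inflow and quantifies
how coil porosity (0.89 vs 0.79) and hematocrit (0.35 vs 0.45) reshape WSS,
OSI, wall pressure and the flow exchanged through the neck.

The package is a desk-scale 2D analogue of a patient-specific 3D problem.
It does not try to reproduce clinical magnitudes; it reproduces mechanisms —
the jet through the neck, the shielded distal dome, porous damping of the
sac — and the direction and rough size of the condition contrasts.

## Geometry and synthetic data

The lumen is the union of a straight channel (width 4 mm) and two
overlapping discs (radii 3 mm and 2.4 mm, centre offset 3.4 mm) that open
into the channel through a 3 mm neck.  The proximal dome is positioned so
its circle intersects the upper channel wall with a chord exactly equal to
the neck width, so "neck width" is a sharp geometric parameter rather than
an emergent one.  The geometry is carried as a Lipschitz level function
(exact signed distance per primitive, min over the union) sampled on a
uniform Cartesian grid; the wall chain is extracted from the zero level set
by marching squares, ordered counter-clockwise, with inward normals from
the analytic level-function gradient.  The open inlet/outlet ends close the
chain but are flagged as non-wall.

The coil is a boolean cell mask filling a prescribed fraction of the sac
(default 1.0, i.e. complete packing), fed from the distal dome tip toward
the neck — the order in which a coil mass accumulates during deployment.

The inlet waveform is a raised-cosine-squared systolic pulse on a diastolic
baseline with a small dicrotic wave: period 0.8 s, diastolic 0.15 m/s, peak
0.55 m/s, systole fraction 0.35 — representative internal-carotid values.
The four cardiac phase markers are detected from the sampled signal:
maximum acceleration and maximum deceleration as the extrema of du/dt
around the systolic peak, and early diastole as the first local minimum of
u after maximum deceleration (the dicrotic notch), which is deterministic
and detectable on any single-peak trace.

What the generator does *not* emulate: patient-specific lumen shape and
curvature, 3D secondary (swirling) flow, inlet waveform variability, and
distensible walls.  Passing tests therefore demonstrate correct mechanics
of the solver and indices under controlled conditions, not clinical
predictive accuracy.

## Rheology

Blood is a regularised Casson fluid,

    mu(gdot) = 0.1 * ( sqrt(eta) + sqrt( tau_y * (1 - e^{-m*gdot}) / gdot ) )^2,
    tau_y    = (0.625 * H)^3,

with `H` the hematocrit fraction, `eta` the Casson plastic viscosity in
poise, `tau_y` in dyn/cm^2, and `m` (s) the exponential regularisation that
keeps mu finite at vanishing shear.  The leading 0.1 is read as the
poise-to-Pa·s conversion, so `mu` is in SI units; with the default
eta = 0.035 poise the infinite-shear viscosity is 3.5 mPa·s, the standard
high-shear value for whole blood.  Defaults: m = 100 s (a standard
Papanastasiou-type regularisation magnitude), rho = 1060 kg/m^3.  The
hematocrit enters only through the yield stress, so raising H stiffens the
fluid at low shear while leaving the high-shear viscosity unchanged — this
is the entire mechanism behind every hematocrit contrast in the study.

## Flow solver

Incompressible laminar Navier–Stokes on a staggered MAC grid with a
first-order projection scheme:

1. **Viscosity** from the previous velocity field: gamma_dot = sqrt(2 D:D)
   at cell centres, then the Casson closure.
2. **Tentative velocity**: explicit second-order upwind advection; the
   viscous term is split IMEX — a constant reference viscosity
   mu_ref = 0.6 * mu(0) is treated implicitly and the variable remainder
   (full variable-viscosity stress divergence) explicitly.  The split is
   unconditionally stable for mu_ref >= mu_max/2 and leaves the *steady*
   discretisation exactly the full variable-viscosity one (the reference
   terms cancel at a fixed point), so the analytic benchmarks are
   unaffected by the split.  The time step is therefore limited only by
   the advective CFL (0.4, re-evaluated every 100 steps from the field,
   with an inflow lookahead so the accelerating systolic front cannot
   outrun the step).
3. **Sinks, pointwise implicit**: Brinkman penalization `-u/eps`
   (eps = 1e-5 s) in solid cells imposes the vessel wall; a Darcy sink
   `-(mu/K) u` in coil cells represents the coil, with Kozeny–Carman
   permeability K = d_w^2 phi^3 / (180 (1-phi)^2) and wire diameter
   d_w = 0.25 mm as the grain scale.  Implicit treatment removes the
   stiffness of small eps and small K entirely.
4. **Projection**: a pressure Poisson solve and divergence-free
   correction.  All implicit systems (two Helmholtz, one Poisson) are
   solved *exactly* by fast diagonalisation: each operator is a Kronecker
   sum of constant-coefficient tridiagonals whose eigenbases are DST/DCT
   variants selected by the boundary folds (the u-momentum x-operator
   carries a rank-one outlet fold handled by a Sherman–Morrison
   correction per transverse mode).  Lumen-cell divergence after each
   step is at machine precision, far below the 1e-6·u_peak/dx contract.

After the projection, a second damp-and-project pass plus a final damping
of the strictly interior solid faces suppress the residual slip that the
pressure kick re-creates in the penalized region; the final damping
touches only faces that border no lumen cell, so lumen divergence is
preserved.  The first face layer around the zero level set is the smeared
immersed wall and is excluded from the slip diagnostic.  Interior slip
scales linearly with eps (halving eps at fixed dt halves it) and sits
around 1e-4 of the peak inlet velocity in the default runs.

Boundary conditions: parabolic inlet profile scaled to the instantaneous
waveform mean (ramped smoothly over the first 5% of cycle 1 to avoid an
impulsive start), zero-gradient outflow with the outlet face as pressure
reference, no-slip on the box walls.  A streamwise-periodic mode driven by
a body force supports the channel benchmarks without entrance-length
contamination.

The numba kernels for advection, diffusion and shear rate replicate the
vectorised numpy reference stencils exactly (a unit test enforces
agreement to roundoff); the numpy path remains and serves the periodic
mode.

## Wall indices

WSS is extracted by normal probes: tangential velocity sampled at 1.5 dx
and 3 dx along the inward wall normal (bilinear interpolation), and the
wall gradient taken as the one-sided second-order difference anchored at
the no-slip wall — exact for locally quadratic profiles, which makes the
plane-channel benchmark (6 mu U / h) accurate to well under 1%.  The wall
viscosity is re-evaluated from the probed shear rate.  In 2D the WSS is a
signed scalar along the chain tangent; OSI uses the signed value, TAWSS
and the maxima the magnitude.

OSI follows the standard Ku definition
OSI = 0.5 (1 - |⟨tau⟩| / ⟨|tau|⟩) with periodic trapezoidal cycle
averages; points with identically zero shear score 0.  Because figures of
per-instant OSI maps need an OSI value *at* an instant, the per-phase
report uses a windowed variant accumulated from cycle start to the phase
instant with ordinary trapezoidal quadrature; the full-cycle OSI is
reported alongside.  Per-phase maxima are taken over valid wall points in
the analysis field of view: the sac wall plus the parent-vessel wall
within two channel widths of the neck (mirroring the region the study's
figures display).  Wall points whose probes fall outside the lumen are
flagged invalid and excluded; the report warns if they exceed 10% of the
field of view.

The neck-plane average velocity samples >= 32 points strictly inside the
neck segment and averages the velocity magnitude — the quantity used by
the grid-convergence harness.

The wall-load export writes pressure and shear traction per wall point and
phase, the one-way coupling surface for an external structural solver;
structural mechanics itself is out of scope.

## Study pipeline

The default study holds geometry and waveform fixed and crosses
H ∈ {0.35, 0.45} with coil state ∈ {uncoiled, phi = 0.89, phi = 0.79}.
Three cycles are integrated from rest and the final cycle is analysed; the
cycle-2 vs cycle-3 peak-systolic max-WSS difference (well under 1%)
justifies discarding the first two.  Contrasts are tabulated as
100·(A−B)/A with the reference first: the porosity chain
uncoiled → 0.89 → 0.79 within each hematocrit, and the hematocrit contrast
0.45 → 0.35 at each coiled porosity (HCT comparisons are framed within
coiled models, matching the study design).  Absolute differences are
tabulated alongside: for Casson blood the *relative* HCT contrast is
largest at low shear, so the statement "the hematocrit effect is largest
at maximum acceleration and peak systole" is a statement about absolute
WSS differences, and the tests assert it as such.

Two condition contrasts deserve explicit framing.  Tightening the coil
from porosity 0.89 to 0.79 lowers the maximum WSS by about 8% at maximum
acceleration — the headline coil effect in this model — while at peak
systole the same contrast measures only ±0.1–0.8%, below the three-cycle
periodicity drift (0.3–0.6%) of the phi = 0.89 runs: once the sac is
packed at all, the peak-systolic wall maximum is set by the channel jet
skimming the neck and is insensitive to the packing density.  Coiling per
se (uncoiled → 0.89) does reduce the peak-systolic maximum, by 4–5%.
Similarly, per-phase OSI maxima saturate near the 0.5 ceiling in 2D (some
wall point always oscillates almost symmetrically), so the porosity effect
on OSI is asserted on the late-phase mean rather than on per-phase signs
that sit in the fourth decimal.  The acceptance script reports all of
these magnitudes so the reader can see exactly where the contrasts are
strong and where they vanish.

Grid convergence uses frozen-inflow steady solves (10x cheaper than full
cycles, same discrimination between grids) at the maximum-acceleration and
peak-systolic inflow levels, reporting the neck-plane average velocity and
flagging the coarsest level within 1% of the finest.  The four levels
(ny = 52, 65, 91, 117, refining dx by ~1.25–1.4x) are chosen as multiples
of 13 so the parent-wall line y = W stays exactly grid-aligned across
levels; non-aligned ladders shift the penalized wall by a fraction of a
cell between levels, which dominates the level-to-level differences of a
metric sampled in the neck shear layer and destroys monotonicity.  With
aligned levels the sequence is cleanly monotone and first order in dx —
the convergence rate of the volume-penalized wall — with a measured
constant such that the two finest grids still differ by about 5%;
agreement at the percent level would need roughly 300 cells across the
domain height.  This slow, regular first-order approach is itself a
verified property of the discretisation and is reported as such.

Problem sizes: the headline study runs at 96 x 192 cells (dx = 0.135 mm,
22 cells across the neck), three cycles per condition, about 2e4 time
steps per condition; the benchmarks use 64 cells across the channel gap.
These sizes keep the full suite — six conditions, four benchmarks, and the
four-level convergence harness — runnable on a single CPU in minutes while
leaving every reported contrast well above discretisation noise.

## Numerical choices and degenerate inputs

- Time step: advective CFL 0.4, safety 1.2 on the instantaneous pointwise
  |u|+|v| maximum, re-evaluated every 100 steps; deterministic (no
  randomness anywhere in the pipeline, so repeated runs are bit-identical
  and the summary CSV is byte-identical).
- Poisson/Helmholtz: exact spectral solves; `poisson_rel_tol` documents
  the contract, the solves reach machine precision.
- Zero inflow with zero initial state is an exact fixed point of the
  scheme.
- Degenerate geometry (both dome radii zero) reduces to a plain channel
  with an empty sac and coil; non-overlapping domes and grids with fewer
  than 6 cells across the neck are rejected at construction.
- OSI quadrature refuses fewer than 16 samples per cycle (the guard can be
  relaxed explicitly for closed-form hand checks); windowed OSI at the
  earliest phase rests on ~11 samples and is correspondingly coarse.
- A constant (zero-amplitude) waveform is rejected: its phase markers are
  undefined.

## Known limitations

- 2D planar flow: no secondary swirl, no out-of-plane neck jet
  structures; sac shear in 2D oscillates more than in 3D, so full-cycle
  OSI maxima saturate near 0.5 in all conditions and discriminate
  conditions weakly — the windowed per-phase OSI and the sac kinetic
  energy are the sharper coil metrics here.
- The coil is a homogeneous porous medium; real coil masses are
  heterogeneous and compact over time.
- The penalized wall is accurate to O(dx) in wall position; WSS at the
  two neck corners sits on a geometric singularity and is grid-sensitive
  there.
- One-way coupling only: wall loads are exported, wall motion is not fed
  back.
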