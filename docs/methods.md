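# Methods

`shapemem` models how a neural progenitor's shape before mitosis can bias
the fates of its two daughters even though the shape itself is erased by
mitotic rounding.  The memory carrier is the membrane ligand Delta: an
eccentric cell loads more Delta near its far, spiky (+) end; rounding and
division then hand the two daughters unequal Delta doses; and Delta–Notch
lateral inhibition amplifies that small dose difference into a binary
V2a/V2b fate decision.  This note documents the model, its parameters, the
synthetic data it runs on, and the numerical and design choices behind the
implementation.

## Shape quantification

A segmented cell is a set of voxels with physical spacing (µm).  With
`C_mass` the unweighted centroid of foreground voxel centres and **I** the
moment-of-inertia tensor about it (unit voxel mass), the eigenvector with
the *smallest* eigenvalue is the long axis `e_long` (mass far from an axis
contributes little moment about it).  Projecting every voxel onto the
three principal axes gives an axis-aligned minimum bounding box; its
centre is `C_median`, and

    D_asym = C_median − C_mass

defines the direction of asymmetric elongation (the (+) side).  All axes
are sign-flipped to have nonnegative dot product with `D_asym`
(`a_long`, `a_middle`, `a_short`), and

    D_long = D_asym · a_long,     A_long = D_long / r,   r = (3V/4π)^(1/3).

`A_long` is dimensionless and invariant under rigid motion and uniform
scaling; a centrosymmetric cell has `A_long = 0`, and observed cells range
up to ≈ 0.12.  Degenerate cases (zero `D_asym`, eigenvalue ties below a
1e−3 relative gap) keep the raw eigenvector signs and carry a flag;
`A_long` is then 0 by construction.

The fate axis `a_CD` points from the V2b daughter to the V2a daughter;
`θ_fate = arccos(a_long · a_CD)` with the sign rule: cos > 0 means the
(+)-side daughter is the V2a.  cos = 0 is reported as a tie flag rather
than an arbitrary call.  Axis changes (e.g. after an induced shape change)
are compared as undirected lines, folded into [0°, 90°], with a 45° cut.

Protein localization uses the intensity-weighted centroid over
mask-restricted voxels: `d = |C_signal − C_mass| / r`, with the (+)-side
call from the sign of `a_long · (C_signal − C_mass)`.  The
surface-to-volume ratio counts exposed voxel faces.  The ROC threshold on
`A_long` maximizes Youden's J (sensitivity + specificity − 1), ties broken
toward the smaller threshold; the criterion is not prescribed by the
original method description, and J is the standard default.

## The Potts model of mitotic rounding

One cell (σ = 1) sits in medium (σ = 0) on a cubic lattice of 0.5 µm
sites with a frozen one-site medium frame.  The energy is

    H = Σ_faces J(σ, σ′) + λ_v (v − V)² + λ_s (s − S)²

with `v` the site count and `s` the surface area.  Metropolis dynamics
attempt one site copy per lattice site per Monte Carlo step (mcs): a
random target site takes the identifier of a random 26-neighbor; the move
is accepted outright when ΔH < 0, with probability exp(−ΔH/T) otherwise
(ΔH = 0 accepted).

**Surface measure.**  Boundary sites and the interfacial term use 6-face
adjacency.  The cortical-tension term and the division trigger do *not*
use the raw face count: face counting measures the sum of a shape's axis
projections, which the cube (not the sphere) minimizes at fixed volume and
which is nearly blind to elongation — a 2:1 prolate body counts only ~5%
more faces than the equal-volume ball, so no face-count trigger can
express "the cell has not rounded yet".  Instead, `s` is a marching-cubes
estimate: overlapping 2×2×2 windows each contribute the triangle area of
their local configuration (a frozen 256-entry table).  The estimator is
strictly local (flipping one voxel changes 8 windows), makes the sphere
the minimizer, and reads digitized balls high by a measured factor ≈ 1.09
(radii 6–12 sites), which scales the sphere target:

    V(σ) = initial volume,    S(σ) = 1.09 · 4πr²,    r = (3V/4π)^(1/3).

**Division trigger.**  The cell divides at the first downward crossing of
`s ≤ s_division_factor · S(σ)`, along the plane through the centroid
perpendicular to the cell vector **CV** (the sum of unit vectors from the
centroid to the blue particles).  Sites exactly on the plane alternate
between daughters to balance volumes; a zero cell vector draws a random
plane and flags the replicate.  After division the daughters keep their
shapes (targets = actual values) while the fate ODE runs; the lattice is
not evolved further, since nothing downstream depends on it.

**Calibrated baseline.**  J_cell–medium = 3, J_cell–cell = 1.5, λ_v = 1,
λ_s = 0.025, T = 3, trigger factor 1.10, total budget 500 mcs.  λ_v and T
keep volume excursions within a few sites and the interface smooth;
λ_s and T set the rounding speed.  The trigger factor is the one genuinely
consequential choice, discussed under *Timescales* below.

## Membrane particles

Two independent site-valued layers live on the cell boundary: blue
particles (cortical force generators, default step 1 lattice length/mcs)
set the division axis; yellow particles (Delta, default step 2) set the
fate.  Counts default to concentration × cell sites — 5.0e−2 per lattice
site gives ≈ 260 particles on the ≈ 5200-site default cell, matching the
published order of "about 80–160 particles per cell" at 2.5–5.0e−2 —
and stay constant from initialization to division.

*Initialization* encodes the shape: repeat { pick a random boundary site
(distance d₁ from `C_mass`), pick a random site of the whole lattice
(distance d₂ from the same centre); place a particle at the boundary site
iff d₁ > d₂ } until the requested count is reached.  Acceptance is
proportional to the ball volume of radius d₁, i.e. ≈ d₁³, so far boundary
(the spiky end) is loaded most heavily.  The uniform alternative places
particles uniformly over boundary sites (the no-memory control).

*Attachment*: after every accepted copy, particles whose site left the
boundary move to a uniformly chosen *nearest* boundary site (Euclidean;
searched over growing cubes, exact because Euclidean ≥ Chebyshev
distance).  *Diffusion*: once per mcs, each particle jumps to a uniformly
chosen boundary site in the open annulus (s − L/2, s + L/2); s = 0 means
frozen; an empty annulus leaves the particle in place (counted).  Note the
annulus at s = 2 contains squared distances {4, 5, 6}, so the single-jump
MSD is ≈ 5, not exactly s²; and at s = 1 the in-plane diagonals (√2) are
reachable alongside the face neighbors.

## Fate: Delta–Notch lateral inhibition

Division partitions the yellow particles by daughter ownership;
`Del_ini = n / N_yellow` per daughter and `Not_ini = 0`.  Each mcs
advances one 4th-order Runge–Kutta step of size dt = 0.5 of

    dNot/dt = F(Del_neighbour) − Not,     dDel/dt = ν (G(Not) − Del)

with F(x) = x²/(a + x²), G(x) = 1/(1 + b x²), a = 0.01, b = 100, ν = 1.
The committed V2b state requires Not = F(1) = 1/(1 + a) > 0.98 and
Del = G(F(1)) ≈ 0.01 < 0.02, so a ≤ 0.02 is structural.  The first
daughter to cross both thresholds is V2b and the sister V2a; integration
then stops.  A modest asymmetry (ε = 0.1) resolves in ≈ 23 mcs and even
ε = 0.01 within ≈ 32, satisfying "several tens of mcs";
`verify_bistability` checks this switch property before ensembles and
rejects parameter sets whose switch only fires from already-committed
starts (e.g. ν = 0).  Exact ties cannot resolve by symmetry and are broken
by a seeded coin flip, flagged.

## Synthetic cells

No deposited cell images exist, so a parametric family stands in for the
segmented cells (synthetic stand-ins, generated in code).  Three features
of real pre-mitotic progenitors compose it:

1. **Elongation** — a prolate spheroid base (aspect 2.5 : 1 at the volume
   of a 10-µm-equivalent-diameter cell).  This is what makes mitotic
   rounding a real, detectable process for the surface trigger.
2. **Asymmetric elongation** — the (+) half has a longer semi-axis (an
   egg silhouette).  This is the feature `A_long` measures.
3. **A spiky (+) end** — five thin (1.5-voxel radius) protrusions leave
   the (+) pole at 30° off-axis, length 60 × taper, with six shorter,
   wider (−)-pole bumps (radius 2.6, length (0.73 − 1.07 × taper) × the
   protrusion length — the egg supplies progressively more (−)-side area
   as the taper grows, so the ballast tapers off) whose lateral area and
   mass lever roughly balance them.  Protrusions and ballast appear only
   as a balanced pair, and the symmetric target snaps to the exactly
   mirror-symmetric member: with ≈ 200+ particles the fate switch
   amplifies even voxelization-level load asymmetries
   (bias ≈ Φ(√N · (2f − 1))), so the null fixtures must be true nulls.

The protrusions matter because `A_long` caps the *extreme* reach
asymmetry (u − w = 2·A_long·r between the two bounding-box reaches), so
smooth convex shapes cannot exceed a d³-weighted (+)-side load of ≈ 0.52
at the observed eccentricities; oblique protrusions carry far-from-centre
boundary area without extending the bounding box, reaching the ≈ 0.55–0.58
loads the fate bias needs.  The (−)-side ballast keeps uniform-by-area
placement unpolarized — the no-memory control must be a true null — and
limits centre-of-mass drift during rounding.  One parameter (the taper)
drives the egg asymmetry and protrusion length together, so symmetric
cells are smooth and eccentric cells are spiky.

`A_long(taper)` is noisy at the voxel level (bounding-box jumps ≈ 0.01),
so the tuner inverts an isotonic fit of a coarse scan — the fixture's
physical asymmetry scales with the requested target — and a sub-voxel
placement offset provides the fine control; all six published targets
(0.002–0.092) are reached within ±0.002.

Synthetic confocal stacks add a linear intensity gradient along a chosen
axis, Poisson shot noise and optional Gaussian blur.  What they do *not*
emulate: anisotropic PSFs, depth attenuation, neighbouring cells, or the
thin-protrusion loss that median filtering inflicts (the end-to-end test
shows the radius-1 median filter thins the 1.5-voxel protrusions and
shifts recovered `A_long` by up to ≈ 0.015 on the most eccentric shape —
real pipelines share this loss).

## Timescales, and what the model can and cannot do at once

Measured on the default cell, the boundary walk erases a hemispheric
Delta load with time constant ≈ 30 mcs at step 2 and ≈ 7 mcs at step 4.
The published unit conversion implies the same in physical units (step 2 ↔
0.042 µm²/s on a 5-µm cell gives ≈ 5 min mixing versus a 21-min rounding
phase).  Consequently a division near 215 mcs would erase the step-2
memory entirely (e^−7), while the perturbation experiments require the
bias to survive at step 2 and vanish at step 4 — which brackets the
division time between the two mixing times.  The default trigger factor
(1.10) therefore fires while rounding is still finishing, at ≈ 30–50 mcs;
the published 21 min ↔ 215 mcs correspondence is kept verbatim as the
unit-calibration arithmetic (`calibrate_units`), not as a property of the
simulated trajectories.

One consequence is a genuine deviation from the published ordering of the
diffusion sweep: during active retraction, mobile Delta is *pumped* into
the retreating (+) front (stranded-particle reattachment is a biased
ratchet), so at early division the step-2 condition is slightly *more*
polarized than frozen Delta (measured (+) fractions 0.536 vs 0.531 at 72
replicates; biases 0.861 vs 0.819).  The ordering
bias(0) ≥ bias(2) ≥ bias(4) therefore holds robustly only in its second
leg; restoring the first leg requires dividing after the pump dies
(≳ 100 mcs), which erases the step-2 memory and the per-shape
significance instead.  The two published patterns are incompatible in this
model class; the implementation keeps the headline shape–fate trend.

## Ensembles and statistics

The desk scale is 48 replicates per shape (published: 144, one flag
away), lattice ≈ 50×33×33 sites, ≈ 0.2 s per replicate.  Per-replicate
seeds derive deterministically from (base seed, shape index, replicate),
so every ensemble is exactly reproducible.  Replicate failures (no
division within 500 mcs, annihilation) are recorded, not fatal.  The
headline readout per shape is the fraction of resolved replicates whose
(+)-side daughter (larger centroid projection on the original `a_long`)
became V2a, tested against 50:50 with the χ² goodness of fit
(df 1; df 2 applies to three-bin orientation tables).  No
multiple-testing correction is applied.  The parameter-fitting mode runs
12 replicates per shape per (concentration, step) candidate and ranks
candidates by squared distance to a user-supplied target bias profile;
the experimentally observed profile is read off a published bar chart and
is therefore an input, not a constant.

## Known limitations

- Division fires during late rounding rather than after a 215-mcs
  rounding phase (see *Timescales*); the retraction pump inverts the
  frozen-vs-slow-diffusion ordering at these times.
- The sparse-Delta condition (5.0e−3 per site, ≈ 22 particles) weakens the
  bias (≈ 0.65–0.73 from ≈ 0.85–0.96) but does not null it: the fate
  switch amplifies a mean load fraction f as Φ(√N·(2f−1)), and
  √22 × 0.1 is not small.  A true null at that concentration would need
  either far fewer particles per cell than the published count or the
  weak-retention regime that erases the shape–fate significance.
- Face-count SAV and marching-cubes areas are digital estimates with
  resolution-dependent bias (documented factors, configurable).
- The two-cell fate stage ignores Delta turnover, cis-inhibition,
  transcriptional noise and any third neighbour.
- The fixture family is a stand-in: it reproduces the eccentricity index,
  the boundary-area null and the distance-cubed load of real cells, not
  their detailed morphology; absolute bias magnitudes therefore depend on
  the family's protrusion geometry, while the orderings and trends are
  the robust outputs.  Mid-eccentricity members (A_long ≈ 0.02–0.03, at
  the protrusion-appearance threshold) can carry residual biases of
  either sign (≈ ±0.1); the calibrated clauses are the symmetric null,
  the asymmetric significances and the perturbation orderings.
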