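# Methods

`cilialign` quantifies how the beating direction of motile cilia responds to
an external shear flow, and models why dense cilia carpets respond less.  It
has three layers: an image-analysis pipeline that turns microscopy movies
into per-cell beat frequencies and beating directions; culture-level
statistics (alignment parameter, densities, shear-stress profiles, a
dose-response fit); and a hydrodynamic model (slender-body Stokes flow of
tilted rod arrays near a wall, balanced against a basal torsional spring).
A synthetic-data layer generates every input with known ground truth so each
stage can be tested in closed loop.

## Beat-pattern coarse-graining (`cilialign.beat`)

A planar beat is stored as the tangent-angle profile ψ(s, t) on an
(arclength × phase) grid, with ψ measured from the in-plane beating
direction ê toward the surface normal.  The centerline is reconstructed by
cumulative trapezoid quadrature of (cos ψ, sin ψ); unit contour length is
preserved by construction and is asserted in tests.

Three summaries feed the rod model:

* **Mean-tangent tilt α** — the unit tangent averaged uniformly over
  arclength and phase (vector average; an angle average is available behind
  a flag).  Uniform measure is used because the beat is summarised along the
  arclength over one period, with no arc-speed weighting.  For ependymal
  beat patterns this tilt is about 53°, which is the default rod elevation.
* **Stroke-extreme chord angles** — the elevation of the base-to-tip chord
  at the phases of maximal forward and backward reach (about 23° and 18°
  for ependymal cilia).  They set the minimum spacing along the beating
  direction, d∥(min) = L(cos 23° + cos 18°) ≈ 1.87 L, so that swept
  footprints of successive cilia do not overlap.
* **Top-view footprint A_top** — the swept length (forward plus backward
  horizontal reach) times a lateral width.  The width defaults to **one body
  width (0.04 L)**, the strip the cilium body itself sweeps in top view;
  with it A_top ≈ 0.075 L².  This choice makes the perpendicular-spacing
  grid d⊥ = 0.08…0.40 L map onto ciliated area fractions ρ = 0.5…0.1,
  bracketing the fractions measured in maturing (≈ 0.09) and mature
  (≈ 0.17) cultures, and reproduces the reported ≈ 2× torque reduction at
  ρ ≈ 0.1.  A two-body-width convention is available by passing
  `footprint_width=0.08`.

Waveforms are inputs, never simulated; the synthetic layer provides a
travelling-bend family ψ = rest + A cos 2π(t − ws) + B cos 4π(t − ws) whose
first even harmonic B controls power/recovery asymmetry, plus a closed-form
construction hitting prescribed stroke extremes (used to plant 23°/18°).

## Slender-body hydrodynamics (`cilialign.sbt`)

Cilia are coarse-grained as **static rigid rods** (length L = 1, radius
r = 0.02 L) tilted 53° from the surface plane toward ê, with bases a gap of
0.05 L above a plane no-slip wall, in an imposed shear flow u = γ̇ z ĝ.  The
force density f(s) along each centerline satisfies the condition that the
total fluid velocity vanishes on every rod (rigid, non-moving rods).

Numerical formulation, for M = 24 nodes per rod (segment midpoints):

* **Intra-rod operator.** The Stokeslet kernel is integrated analytically
  over each straight segment, evaluated on the rod surface at the target
  node (radial offset equal to the local radius, circumferentially
  averaged).  For a straight filament this reproduces the classical
  slender-body drag logs including their O(1) constants, and it is
  unconditionally stable in M because the radius regularizes the kernel.
  The default **spheroidal radius profile** r(s) = 2r√(s(1−s)) gives the
  canonical uniform drag coefficient along the rod (the slender-body theory
  of a spheroidal-ended filament); a constant-radius profile is available
  (`radius_profile="cylindrical"`) and yields ≈ 14 % higher isolated-rod
  torque because a cylinder's ends carry more drag.
* **Rod–rod coupling.** Midpoint-quadrature Stokeslets between centerline
  nodes of different rods.  The finite-radius source-doublet correction is
  omitted here: the closest approach is 4 radii, where it is an O((r/d)²) ≤
  6 % correction to the coupling terms only, and omitting it lets the wall
  condition be exact (next point).
* **Wall.** The exact Blake image system for every Stokeslet.  The total
  velocity field therefore vanishes on the wall plane to machine precision,
  which is asserted in the tests.
* **Torque.** The z-torque about the vertical axis through each rod base
  (the axis about which the beating direction can re-orient), from the
  quadrature of (x − base) × f, reported in units of ηγ̇L³ with the sign
  positive when the torque rotates ê toward the flow.

With these defaults the isolated rod at θ = π/2 experiences T₀ ≈ 0.60,
converged to 0.04 % between M = 16 and M = 32, within 9 % of the reference
value 0.55 for this configuration (whose exact discretization and image
formulation are not fully specified; the remaining difference is of the size
of legitimate slender-body formulation choices).

**Screening sweep.** Arrays are rectangular lattices (default 9 × 9), rows
along ê at the minimum spacing d∥(min) — widening d∥ further changes
torques by < 5 %, which is asserted — and columns across at d⊥ ∈
{0.08, 0.16, 0.24, 0.32, 0.40}.  Because rotating the imposed flow instead
of the lattice leaves the system matrix unchanged, each density is
factorized once (LU) and all flow angles θ are back-substitutions.  The
table reports the all-rod average torque normalized by T₀(π/2); the central
rod is available for diagnostics and a lattice-size convergence utility is
provided.  Ciliated area fraction is ρ = A_top/(d∥ d⊥).  On the 9 × 9
lattice the normalized torque at θ = π/2 falls monotonically from ≈ 0.53 at
ρ = 0.1 to ≈ 0.25 at ρ = 0.5 — the hydrodynamic screening effect: at the
mature-culture density the external flow's grip on each cilium is roughly
half of what an isolated cilium feels, and it keeps dropping with density.

Problem sizes: a 9 × 9 × M = 24 sweep is a dense 5832-unknown solve per
density (seconds to tens of seconds each); the defaults keep the full sweep
in the low minutes on one core.

## Torque balance (`cilialign.alignment`)

Re-orientation is resisted by an effective torsional spring at the base
(the phenomenological stand-in for the apical actin mesh the cilia are
anchored in): T_el = k (π/2 − θ), zero at the rest angle π/2 (beating
initially perpendicular to the imposed flow), linear in θ, with k
non-dimensionalised by ηγ̇L³.  The equilibrium angle θ* solves
T_hydro(θ*) = T_el(θ*); the alignment parameter of the model cilium is
Φ = cos θ*.

The sampled hydro curve is interpolated with a monotone piecewise-cubic
(PCHIP) — chosen because it cannot overshoot and hence cannot create
spurious crossings — bracketed on a 2048-point grid and polished with
Brent's method.  k = 0 returns full alignment; if the elastic torque
exceeds the hydrodynamic torque everywhere the rest-angle boundary solution
is returned flagged; multiple crossings return the smallest θ with a
warning.  Every equilibrium is cross-checked in tests against a 10⁴-point
brute-force scan of the torque balance (< 10⁻³ rad).  Applying this per
(ρ, k) cell of the screening table yields the alignment surface Φ(ρ, k),
monotone non-increasing in both arguments: stiffer anchoring or denser
carpets align less.

## Movie pipeline (`cilialign.pipeline`)

Inputs are a fast bright-field stack (default 160 frames/s for 5 s) and a
slow fluorescent tracer stack (10 frames/s for 10 s) of the same field of
view, with pixel size defaulting to 0.2375 µm (so a 32 px box is 7.6 µm,
about one multiciliated cell).

1. **Activity map**: per-pixel temporal standard deviation, min–max
   normalized; beating cilia light up.
2. **Otsu mask**: 256-bin Otsu threshold on the activity map.  On a pure
   noise field Otsu necessarily splits near the middle of the unimodal
   histogram; downstream gates (next steps) are what reject those pixels.
3. **Per-pixel CBF**: the highest peak of the magnitude spectrum in a 1–50
   Hz band (DC excluded; band must sit below Nyquist).  Resolution is
   frame_rate/n_frames = 0.2 Hz at the default acquisition.  A prominence
   score (peak power over median in-band power) flags noise pixels: pure
   noise scores ≈ 8–15, genuine beating ≫ 100; the default gate is 30.
4. **Cell segmentation**: region growing over validated pixels with
   8-connectivity; a component absorbs a neighbour only while its frequency
   standard deviation stays ≤ σ_f (default 1.0 Hz — above the 0.2 Hz FFT
   resolution, below typical between-cell CBF differences), and components
   under 20 px are dropped.  Touching cells beating at distinct
   frequencies split.
5. **PIV**: per 32-px interrogation box, consecutive frames are
   cross-correlated via zero-padded FFT correlation normalized by the
   per-lag overlap area (plain circular correlation biases displacements
   toward zero), with a three-point Gaussian sub-pixel fit; displacements
   are averaged over all frame pairs (single pass, no overlap, so the
   vector grid matches the box grid exactly).  Textureless boxes are
   invalid.  Rigid translations are recovered to < 0.1 px.
6. **Merge**: boxes with ≥ 10 % ciliated pixels and a valid non-zero PIV
   vector become cell records (box centroid, mean CBF of cell pixels in the
   box, velocity, unit direction p̂ = v/|v|).  An optional registration
   check (phase correlation of mean frames) refuses to merge when the two
   movies have drifted by more than 2 px; it is off by default because
   bright-field and tracer movies of synthetic data share no structures.

## Culture statistics (`cilialign.stats`)

* Alignment parameter Φ = (1/N) Σ p̂ᵢ·ê and net flow V̄ = (1/N) Σ vᵢ·ê (mean
  projections; a vector-mean-magnitude variant is behind a flag).  When FOV
  ids are given, Φ is computed per FOV and averaged with its standard error.
* Densities: ρ_cell = N_box/(N_tot·A_box) in cells/mm², ρ = N_box/N_tot.
  At the 7.6 µm box size an area fraction of 0.17 corresponds to
  ≈ 2.9 × 10³ cells/mm².
* Channel shear: τ(x) = 6ηQ/(h² w(x)) with w(x) = w0 + slope·x (Hele-Shaw).
  The default geometry (h = 1 mm, w: 1 → 5 mm over 7 mm, i.e. a 15°
  half-angle taper) spans a five-fold stress range in one chip; a
  segment-mean helper averages τ over sub-segments of the taper.
  The near-wall stress scale of a measured flow is ηV/h (1 Pa = 10
  dyne/cm²), with viscosity defaulting to 0.8 mPa·s (culture medium at
  37 °C), always echoed in outputs.
* Dose response: Φ(τ) = 1 − exp(−τ/τ_c) fitted by nonlinear least squares
  for the single parameter τ_c; the curve passes through 1 − 1/e ≈ 0.63 at
  τ = τ_c by construction.  The confidence interval is a percentile
  bootstrap over resampled (τ, Φ) pairs (default 68 %) rather than an
  asymptotic interval, because condition-level samples are small and the Φ
  noise heteroscedastic.

## Synthetic data (`cilialign.synthetic`)

The generators emulate the acquisition conditions: 512² px fields with 150
cells of radius 8–14 px, CBF ~ N(25, 3²) Hz, directions von Mises with
κ = 4 about the flow axis (E[Φ] = I₁(κ)/I₀(κ) ≈ 0.86), bright field at 160
frames/s for 5 s (16-bit, baseline 1000, oscillation amplitude 150,
per-pixel random phase, read noise 40), tracers of 1 µm at 10 frames/s for
10 s, 2500 particles (≥ 5 per interrogation box), advected by per-cell
Gaussian flow patches of width 8 px — about one cell radius, so each box's
flow reflects the cell beneath it — peaking at 10 µm/s, with 0.05 µm
Brownian jitter per frame.  Every generator is bit-reproducible given its
seed.

What the generators do **not** emulate: phase coordination within and
between cells (metachronal waves), out-of-plane flow and particle defocus,
photobleaching, drift, or heterogeneous cell shapes.  Recovery tests
therefore demonstrate that the pipeline's inference is correct under its
own model assumptions — frequency content localized on cells, flow locally
parallel to the cell's beating direction — not that those assumptions hold
in any particular culture.  Note also that overlapping flow patches of
neighbouring cells smooth the measured direction field slightly toward its
local mean, which biases recovered alignment upward by ≈ 0.02 at the
default density; the recovery tolerance (0.05) accounts for this.

The dose-response generator plants τ_c values of 0.05–0.1 dyne/cm² on the
experimentally used stress grid τ ∈ [0.02, 0.8] dyne/cm²; at n = 30 points
with σ = 0.05 noise, the fit recovers τ_c with ≈ 2–3 % median relative
error and the bootstrap 68 % CI covers the truth in ≈ 65 % of replicates.

## Numerical choices and limitations

* Dense direct solves (LAPACK) for the slender-body systems; fine to a few
  ×10³ unknowns.  No periodic boundary conditions: the lattice is finite,
  so the all-rod average under-screens relative to an infinite carpet;
  `lattice_convergence` quantifies the array-size dependence.
* Rods are static: no time-resolved beating, no filament elasticity, and
  the torsional spring is phenomenological (statics only, no relaxation
  dynamics, no viscoelastic anchoring).
* The headline culture measurements (Φ ≈ 0.9 at 0.8 dyne/cm², τ_c values,
  cell densities) depend on raw movie data that are not distributed with
  the package; they appear here only as planted ground truths for recovery
  tests.
* Degenerate inputs: constant movies yield a zero activity map (warned);
  single-valued maps yield an empty Otsu mask (warned); k = 0 springs and
  boundary equilibria short-circuit analytically; Φ > 1 dose-response
  inputs are clipped with a warning.
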