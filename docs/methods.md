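# Methods

## Problem and model

`chambergrow` designs the *healing chamber* of a threaded dental implant —
the recessed region between threads that is not in bone contact at
placement, fills with blood clot and woven bone, and largely determines
secondary (biological) stability. Instead of picking a chamber
cross-section a priori, the package "grows" one: it simulates
strain-driven bone remodeling around the implant and, every time the
simulated bone would resorb an element of chamber bone, back-fills the
vacated voxel with implant material (feasible only for additive
manufacturing, which can print arbitrary voxel geometry at ~50 µm powder
resolution). Where remodeling would deposit bone, an adjacent implant
voxel is ceded back. Each iteration of this process is a candidate
chamber geometry; candidates are ranked by the volume fraction of
*healthy* surrounding bone, i.e. bone at equivalent strains of normal
function.

The mechanical model is linear elasticity on a regular voxel lattice:
every non-void 50 µm cube is one 8-node trilinear hexahedron with full
2×2×2 Gauss integration. Bone and implant elements share lattice nodes,
which is exactly a bonded (fully osseointegrated) interface; no contact
elements, friction or separation are modeled, so each design iteration
costs a single linear solve. Materials are isotropic and linear: cortical
bone 13.7 GPa / ν 0.3, cancellous (type IV posterior-jaw) bone
0.69 GPa / ν 0.3, Ti6Al4V 110 GPa / ν 0.35.

## Geometry

The bundled geometry is a synthetic, axisymmetric stand-in for a
commercial threaded implant in a posterior-maxilla-like bone block (a
proprietary CAD thread form and an anatomical maxilla would change the
numbers, not the method; the design loop is geometry-agnostic). It
consists of:

* a rectangular bone block (cancellous body, cortical crest layer on
  top), mesial/distal faces fully constrained;
* a titanium cylinder inserted from the top, its abutment protruding
  above the crest; the thread helix is collapsed into annular rings at
  the thread pitch (a standard axisymmetric approximation at this mesh
  resolution);
* rectangular circumferential troughs recessed into the core between
  adjacent thread rings. Trough depth defaults to half the thread pitch
  and trough height to the inter-thread gap minus one voxel of clearance
  per side. The troughs start filled with cancellous bone and constitute
  the *design region*: only there may the loop swap bone and implant
  voxels. Threads, core and all bone outside the troughs are immutable.

All dimensions must be whole multiples of the voxel edge (default
50 µm); surfaces are snapped to the lattice, with no partial-volume
elements. The default model is 48×48×72 voxels (2.4×2.4×3.6 mm): core
radius 0.4 mm, embedded length 2.2 mm, pitch 0.5 mm, thread depth
0.15 mm, four thread rings, three troughs (depth 0.25 mm, height
0.3 mm).

The evaluation ROI is a cylindrical shell around the implant (outer
radius = thread radius + 0.5 mm by default, spanning the embedded
length, implant voxels excluded). Published figures of this kind of
region never state its dimensions, so the margin is a configuration
parameter; the healthy-bone *fraction* is fairly insensitive to it
because both numerator and denominator grow with the shell.

## Loading

A compressive axial force is applied on the abutment top face, spread
uniformly over its nodes (a face-area-consistent option exists and is
what the analytic tests use, since it reproduces a uniform traction
exactly). The default magnitude, 3.0 N, is chosen by the scaling
argument F = E_cancellous · ε_target · A_block with ε_target = 750 µε
(mid physiological window) and A_block = (2.4 mm)²: it loads the
miniature default model to the same strain regime a functional occlusal
load (~100 N) produces around a full-size implant, which is the regime
in which the remodeling windows are meaningful. Force on a model is a
condition of the experiment, not a tuning knob: all tests and the
acceptance script use this default.

## Remodeling law

For each design-region bone voxel in face contact (6-connectivity) with
the implant, the signed action probability is

    f*(Γ, ε) = -1                                   ε < ε_du
               -(1-t) + t·f(Γ),  t=(ε-ε_du)/(ε_pl-ε_du),   ε_du ≤ ε < ε_pl
               f(Γ)                                 ε_pl ≤ ε < ε_pu
               (1-s)·f(Γ) + s,   s=(ε-ε_pu)/(ε_ol-ε_pu),   ε_pu ≤ ε < ε_ol
               +1                                   ε_ol ≤ ε

with ε the element equivalent strain, f(Γ) = clamp(Γ/Γ_u, -1, 1), and
Γ = (σ_c − ⟨σ⟩_w)/⟨σ⟩_w the relative deviation of the element's von
Mises stress from the inverse-distance-weighted mean over bone elements
within the sensing radius (default 150 µm = 3 voxels). f* is continuous
and monotone in ε. A negative f* removes bone with probability |f*|
(the voxel becomes implant); a positive one adds bone with probability
f* (one face-adjacent design-region implant voxel becomes bone).

The equivalent strain is the von Mises-type invariant
ε_eq = [1/(1+ν′)]·√[((e₁−e₂)²+(e₂−e₃)²+(e₃−e₁)²)/2] over principal
strains. ν′ defaults to the element material's Poisson ratio; the
incompressible convention ν′ = 0.5 used by some FE postprocessors is
available as an option (for the uniaxial states that dominate this
load case the two differ only by a constant factor; thresholds would be
rescaled accordingly).

Numeric window thresholds are frequently left to cited prior work in
this literature; the defaults here are ε_du = 100 µε, ε_pl = 400 µε,
ε_pu = 1500 µε, ε_ol = 3000 µε, chosen so the pass-through window
coincides with the 400–1500 µε healthy range of the evaluation metric
and with classic Mechanostat disuse/overload levels. All four are
ordinary config entries. Γ_u defaults to 1 (saturation when an element
carries twice, or none of, its neighborhood's stress); a formal source
for this scale does not exist, and results are qualitatively stable in
its vicinity because deep-chamber decisions are dominated by the
deterministic disuse branch.

Γ is defined as 0 when the weighted neighborhood mean is not positive
(e.g. a completely unloaded model): with no stress contrast there is no
nonuniformity signal, and the window law alone decides. The scalar
`nonuniformity()` helper, by contrast, raises on an empty neighborhood
or non-positive mean, since for a single element that is a usage error.

## Design loop

Per iteration, on the frozen solution of the current geometry:

1. interface bone voxels are enumerated in ascending linear (x-fastest)
   index order — a fixed order that makes stochastic runs bit-for-bit
   reproducible per seed;
2. f* is evaluated and one action drawn per element; the sweep is
   repeated `n_act` times (activation frequency, default 1) without
   re-solving;
3. within a sweep, removals are applied before additions; an implant
   voxel created by a removal in the same sweep is ineligible as an ADD
   target; an ADD converts the eligible face-adjacent design-region
   implant voxel with the lowest linear index (a deterministic,
   orientation-stable tie-break);
4. bone voxels added during a step carry no frozen stimulus and simply
   wait for the next solve.

The updated geometry is then re-solved and recorded as the next
candidate together with its metrics — every candidate is thus scored
with the FE solution of its own geometry. The loop stops at `max_iter`,
when a step changes nothing, or when the design region is entirely
implant. Chamber bone is stress-shielded by construction, so the
uniformity-seeking rule fills the chamber monotonically in the mean;
the optimum is typically an intermediate iteration, which is why all
candidates are kept.

Two invariants hold by construction and are enforced by tests: the
design region never contains void and its voxel count is constant
(bone + implant only trade places), and nothing outside the design
region ever changes.

## Evaluation

* healthy-bone fraction: ROI bone voxels with 400 µε ≤ ε_eq ≤ 1500 µε
  (inclusive ends — a measure-zero choice fixed for reproducibility)
  divided by all ROI bone voxels. Published values of this quantity are
  ambiguous about the denominator; dividing by total ROI volume is
  available as `denominator_mode="total_roi"`.
* bone–implant contact area: shared bone/implant voxel faces × h².
  Voxelized area overestimates smooth-surface area (it measures the
  staircase surface), but all candidates share the bias, so ranking and
  relative gains are meaningful.
* best candidate: maximal healthy fraction; ties broken by earliest
  iteration, then larger contact area.

## Numerical choices

* Assembly: one precomputed 24×24 element stiffness per phase scattered
  into a global CSR matrix; symmetric to ~1e-13 relative (summation
  order), enforced to be SPD on the constrained DOFs.
* Solver: SuperLU direct factorization below 6000 free DOFs, otherwise
  Jacobi-preconditioned conjugate gradients at relative residual 1e-9,
  warm-started from the previous iteration's displacement (the geometry
  changes by a thin shell per iteration, which cuts CG iterations
  several-fold). Every solve verifies its residual and raises on
  singular or disconnected systems.
* Strains are evaluated at the element centroid only; for these regular
  trilinear elements the centroid value equals the Gauss average for
  linear fields.
* Default run sizes: the bundled model (48×48×72, ≈448k DOF) solves in
  tens of seconds per iteration on one core; the test suite exercises
  the full loop on this model once per session and uses an 18×18×28
  miniature everywhere else.

## What the synthetic model does and does not show

The generator emulates the *situation* of a threaded implant in
posterior-maxilla-like bone — a stiff crest, compliant cancellous body,
stress-shielded troughs, axial functional load — at reduced physical
scale. It does not include an anatomical bone envelope, helical thread
geometry, CT-derived density fields, nonlinear interfaces or healing
time courses. Passing tests therefore demonstrate the correctness of
the machinery (FE, law, loop, metrics) and the qualitative behavior of
the method (shielded chamber bone resorbs; the chamber fills; an
intermediate candidate maximizes healthy bone and raises contact area);
they do not validate absolute fractions or areas for any commercial
implant. Likewise the remodeling law is phenomenological: it encodes
Wolff/Mechanostat-style strain windows, not cell biology, and its time
step ("iteration") has no calendar units.

One behavior of full-scale anatomical models does *not* transfer to the
bundled miniature: an interior optimum over iterations. In the default
run the chamber bone sits below the physiological window for its whole
life (≈150–380 µε), so it never contributes healthy volume, and
back-filling it with titanium strictly improves load transfer to the
surrounding bone (the healthy-bone count rises monotonically and no
element is ever driven above 1500 µε). The best candidate is therefore
the fully filled chamber, and the contact area of that smooth end state
is below the initial trough's. An interior peak requires a regime in
which partially filled chambers first lift their remaining bone into
the healthy band — which needs the larger bone envelope and load of a
full-scale model, both outside this package's synthetic stand-in. Runs
at higher loads or with other geometries can be configured, but the
defaults are fixed as the package's reference conditions.

## Known limitations

* Single static load case; no load spectrum or fatigue.
* Discrete element swaps can stall in stochastic mode for small |f*|;
  runs are capped by `max_iter` rather than guaranteed to converge.
* The voxel surface is a staircase: exported STL areas are exact for
  the voxel solid but larger than any smoothed manufactured surface.
* CG at 1e-9 with a Jacobi preconditioner is robust but not optimal;
  very large grids would want a multigrid preconditioner.
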