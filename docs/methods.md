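# Methods

`airwaymech` simulates exhalation-driven collapse of an idealized infant
trachea to study how tracheomalacia — focal weakening of the airway wall —
turns gradual narrowing into abrupt, life-threatening collapse.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic test problems do and do not establish.

## Tissue model

All four airway tissues (cartilage rings, inter-ring fibrous tissue,
trachealis smooth muscle, mucosa) are isotropic, nearly incompressible
hyperelastic solids with a one-term Ogden strain energy in principal
stretches λᵢ,

  W = (a/b)(λ̄₁ᵇ + λ̄₂ᵇ + λ̄₃ᵇ − 3) + ½κ(ln J)²,   λ̄ᵢ = J^(−1/3) λᵢ,

with a in MPa and b dimensionless.  The implementation accepts N terms but
defaults to one, which is what the per-tissue coefficient pairs describe:

| tissue        | a (MPa) | b     |
|---------------|---------|-------|
| cartilage     | 0.109   | 16.63 |
| fibrous       | 0.01    | 11.05 |
| smooth muscle | 0.08    | 6.29  |
| mucosa        | 0.1     | 3.4   |

These pairs are fits to published uniaxial preterm-lamb tracheal data
(cartilage, fibrous, muscle) and engineered oral mucosa; the source curves
are not deposited anywhere, so the package's synthetic generator emulates
them by sampling the closed-form uniaxial response (see below).
Viscoelasticity, anisotropy and tension–compression asymmetry are out of
scope: collapse happens fast relative to tissue relaxation times and no
pediatric viscoelastic data exists to calibrate against.

Incompressibility is enforced with a decoupled volumetric penalty
U(J) = ½κ(ln J)², κ = 1000 × Σa per material by default.  κ is a numerical
parameter, not a measured bulk modulus; 1000 × Σa keeps volumetric strains
below ~0.2% of deviatoric ones while leaving the tangent well-conditioned.
The single-element benchmark quantifies the residual compressibility bias:
reaction stress within 0.3% of the incompressible closed form for mucosa at
50% strain, within ~1.1% for cartilage (whose b = 16.63 amplifies the
bias), which is why the cartilage tolerance in the tests is 2%.

Uniaxial fitting (`OgdenModel.fit`) minimizes Σ(σ_model − σᵢ)² on Cauchy
stress under the incompressible uniaxial closed form
σ = a(λᵇ − λ^(−b/2)), λ = 1 + engineering strain, over (log a, log b) with
BFGS from multiple starts: b log-spaced on [1, 20] (8 starts by default)
with the optimal a solved in closed form at each start, because the model
is linear in a at fixed b.  The multistart grid is deterministic; the seed
only jitters starts beyond the first eight.  Compressive data points, if
present, enter the same residual.  R² = 1 − SS_res/SS_tot.

## Geometry

The idealized trachea is 50 mm long with a semicircular lumen of diameter
6, 8 or 10 mm.  "Diameter" is the inner (lumen) diameter.  The anterior
wall is 0.8 mm thick in total — a 0.2 mm mucosal lining plus 0.6 mm of
cartilage or fibrous tissue — following the clinical convention that wall
thickness includes the mucosa.  The mucosa lines the semicircular lumen
only; the posterior wall is a flat, bare trachealis-muscle slab, 0.8 mm
thick, spanning the full outer width of the arc and bonded to the arc ends
by shared nodes.  Axially the wall alternates 2 mm cartilage rings and
1 mm fibrous gaps, starting and ending with cartilage: 17 rings + 16 gaps
tile the 50 mm exactly.

Malacia is modeled by property substitution on a centered span:

* anterior "soft": the n centermost cartilage rings take the fibrous
  coefficients (n ∈ {1, 3, 5, 7}, spans 2/8/14/20 mm including interior
  gaps, which are already fibrous);
* anterior "mucosa": cartilage and fibrous both take the mucosa
  coefficients over the same span;
* posterior: the muscle takes explicit (a, b) — the study uses (1, 7) and
  (1, 1) — over a centered axial length of 2–32 mm.  Note these "reduced"
  coefficients have a *higher* small-strain modulus (ab/2 = 3.5 and
  0.5 MPa) than intact muscle (0.25 MPa) but much weaker large-strain
  stiffening; they are implemented literally as printed.

The mesh is structured hexahedral: a 2-D cross-section (polar half-annulus
patch + rectangular slab patch, merged at shared nodes) extruded through
the ring/gap bands.  A node plane is always inserted at z = L/2 so the
mid-length lumen polygon is exact.  Two density presets matter:

* `TracheaConfig.coarse()` — 8 circumferential divisions; used for the
  posterior runs and smoke tests (≈1100 elements);
* the bending-resolved mesh (16 circumferential divisions, used for the
  anterior collapse studies, ≈1900 elements).  Trilinear hexahedra carry
  parasitic shear in bending, and the snap-through mechanism is a bending
  (arch-inversion) instability: at 8 divisions the anterior arch is
  numerically too stiff to buckle at all, at 12 the limit point appears,
  and at 16 the onset force is within ~25% of its mesh-converged value
  (Richardson extrapolation of the 12/16 pair).  Collapse onset forces
  from the coarse presets are therefore upper bounds; they sit above the
  fully-converged value and well above the published forces for the same
  scenario, which is the main known bias of the scaled-down meshes.

## Finite elements and solver

Total-Lagrangian 8-node hexahedra.  Stress and consistent tangent are
evaluated spectrally from the SVD of F (principal stretches and
directions), with l'Hôpital limits for near-coincident stretches, so the
residual is the exact gradient of the total energy — verified against
finite differences to ~1e−10.  The volumetric penalty is integrated at the
element centroid and the deviatoric part at the 2×2×2 Gauss points
(selective reduced integration) to avoid volumetric locking at
κ/a = 1000.

Exhalation is a follower pressure on the luminal surface: traction along
the deformed inward facet normal, with the consistent (nonsymmetric) load
stiffness.  Pressure is net inward (external minus internal) in cm H₂O;
1 cm H₂O = 98.0665 Pa.  Total airway force is reported as
pressure × undeformed luminal area, a per-model constant (≈0.126 N per
cm H₂O for the 10 mm model, so 40 cm H₂O ≈ 5 N).

Self-contact of the lumen is a frictionless node-to-facet penalty: every
luminal node is tested against opposing luminal facets (topological
neighbors excluded, opposing-normal filter), penetration is penalized
along the facet normal with stiffness 100 × max a / mucosa thickness, and
each of the two symmetric passes carries half the penalty.  The force law
is C¹-regularized: pairs engage with zero force and stiffness at a
standoff of half the mucosa thickness and blend quadratically into the
linear penalty, so Newton does not chatter on the activation kink.  The
stiffness uses the constant-normal approximation; Newton then converges
linearly rather than quadratically in contact-dominated steps, which the
adaptive stepping absorbs.

Boundary conditions (the source description is silent): both end
cross-sections are held axially (z), the muscle midline is held laterally
(x), and the midline end nodes are held vertically — the minimal set that
removes rigid modes while letting every cross-section, including the ends,
deform in-plane.  Malacic spans are centered 15+ mm from the ends.

Load control marches 0 → 40 cm H₂O with adaptive substeps (halve on
failure, ×1.5 after ≤6-iteration convergence, clamped to [1e−3, 4] cm H₂O)
and records states at every 4 cm H₂O.  Convergence: relative residual
1e−6 (against the external load norm, or the initial imbalance for
displacement-driven problems), displacement increment 1e−8, 25 iterations.
A converged step whose displacement rate (‖Δu‖/Δp) jumps by more than
25× the previous step is rejected as a loss of path continuity — that is
Newton hopping dynamically across a limit point, which load control must
report as collapse, not convergence.  When the substep falls below its
floor the run terminates as `non_convergence_collapse`, mirroring how
severe malacia manifests in load-controlled simulation.

Arc-length continuation (cylindrical constraint ‖Δu‖ = Δl) solves the
bordered system — tangent matrix augmented with the load-vector column
and the constraint row — at every corrector iteration; the bordered
matrix stays regular at load limit points where K alone is singular, so
the method can turn folds.  It reproduces the shallow-truss limit load to
0.01% against the brute-force path scan.  For post-collapse trachea
states a second route is provided
(`collapsed_equilibrium_at_force`): load control locates the limit
pressure, viscous (pseudo-dynamic) settling — Newton on
``r(u) + alpha (u - u_k)`` with annealed damping — rides the snap toward
the contact-stabilized branch, and plain Newton then walks that branch to
the requested force level.  Both drivers are deterministic; there is no
randomness anywhere in the solver.

A known limitation at the study meshes: for the severe anterior cells the
limit point coincides with first wall contact, and inside that engagement
zone the trilinear elements must fold the thin mucosa lining through
sharp hinges.  Node-to-facet pair switching and element inversion there
defeat the arc-length corrector and the settling alike, so the collapsed
(post-snap) branch is generally *not* reachable at these densities — runs
end at the limit point, which is reported as the collapse event.  The
smoothed contact activation (below) mitigates but does not remove this.

Wall strain is the per-element maximum principal Green–Lagrange strain
E = ½(FᵀF − I) at element centroids (the displayed strain measure of the
source figures is unstated; this is the standard finite-strain choice).

## Collapse metrics

The lumen area ratio is the area of the deformed mid-length lumen polygon
divided by the intact undeformed area (exactly 1 at zero load by
calibration).  Areas use the shoelace formula via shapely; post-contact
self-intersecting loops are repaired and the largest simple sub-loop is
measured, the analogue of outlining the remaining open lumen in an image.

Instability onset: at output step i ≥ 2, predict the area ratio by linear
extension through the two previous (force, ratio) points; onset is the
first step falling short of the prediction by more than δ = 0.05
area-ratio units (no numeric threshold is published; 0.05 separates the
visible snap drops from linear descent at the 4 cm H₂O cadence, and the
criterion never fires on affine curves regardless of δ).  A run that dies
under load control with no flagged step reports onset at its final step.
Onset is reported in both pressure and force; cross-diameter comparisons
use force.

## Synthetic data and what the tests show

* Stress–strain curves are sampled from the closed-form uniaxial response
  on strains 0–0.50 (step 0.01, the plotted range of the source data),
  optionally with additive or multiplicative Gaussian noise (seeded).
  Noise-free refits recover the generating coefficients to <0.1%;
  multiplicative 5% noise lands refits in the R² ≈ 0.97–0.99 band.  This
  closes the fitting loop but says nothing about how well one-term Ogden
  represents real tracheal tissue — that calibration lives in the
  published coefficients.
* The single-element cube and the thick-walled ring validate the element,
  the assembly and the pressure load against closed forms (Lamé at
  matched small-strain moduli for the ring, 5% tolerance at 0.1 cm H₂O).
* The shallow two-bar von Mises truss validates snap-through mechanics:
  its 1-DOF equilibrium path is scanned densely as a pure function
  (solver-independent oracle); arc-length reproduces the limit load to
  <1% and load control fails just above it.  This validates the
  *drivers*; the trachea's own limit point has no closed form.

The synthetic trachea reproduces the qualitative published behavior —
near-linear intact descent, snap-through for severe anterior malacia with
larger diameters collapsing at lower force, posterior softening that
narrows but never snaps — but its onset forces are mesh-biased upward (see
Geometry) and its idealized geometry omits taper, ring asymmetry and
image-derived cross-sections, so quantitative onset values should not be
read as patient-scale predictions.

## Problem sizes

Default analysis meshes are deliberately small: the coarse preset
(~1100 elements) for posterior and smoke runs, the 16-division mesh
(~1900 elements) for anterior collapse and the post-collapse strain
measurement.  A full anterior collapse trace takes a few minutes on one
core at these sizes.

## Known limitations

* Onset forces converge from above with mesh density; the reported coarse
  values overestimate the converged ones by ~20–50%.
* Trilinear hexahedra + penalty contact smear the sharp fold hinges of
  deep collapse, so post-collapse peak strains are lower bounds.
* No fluid–structure coupling: pressure is spatially uniform, so dynamic
  flow limitation is outside the model.
* The posterior "reduced" coefficients are implemented as printed even
  though their small-strain stiffness exceeds the intact muscle's; the
  units/scale of those printed values are an open question of the source.
* The two geometry ambiguities (inner vs outer diameter; wall thickness
  inclusive of mucosa) are resolved as inner and inclusive; both choices
  are config fields, not hard-coded.
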