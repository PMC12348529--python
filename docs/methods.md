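# Methods

`cogsim` simulates the mechanical reinforcement that barbed (cog) PCL
threads provide to the prolapsed vaginal wall.  This note records the
models, the tunable parameters, the numerical choices, and what the
synthetic stand-in geometry can and cannot establish.  Units are a
consistent mm-N-MPa system (pressures also accepted in cmH2O,
1 cmH2O = 98.0665 Pa); axes are x antero-posterior, y supero-inferior,
z lateral.

## Constitutive models

**Threads (PCL).** Isotropic linear elasticity, E = 367.69 MPa (the
initial slope of the uncut-filament tensile curve) and nu = 0.3.  Thread
simulations stay below a few percent strain, inside the elastic range,
so the solver treats linear-elastic materials geometrically linearly as
well (engineering strain); a displacement-driven thread problem then
solves exactly in one Newton iteration.  Viscoelasticity and plasticity
of PCL are out of scope.

**Tissue (vagina/uterus).** Incompressible Ogden hyperelasticity in
principal stretches.  Two parameterizations circulate:

* classical: `W = sum_n (mu_n/alpha_n) (l1^a_n + l2^a_n + l3^a_n - 3)`,
  ground-state shear modulus `mu0 = 0.5 sum(mu_n alpha_n)`;
* solver (Abaqus-style): `W = sum_n (2 mu_n/alpha_n^2) (...)`,
  `mu0 = sum(mu_n)`.

The published three-term vagina/uterus set
(mu = -92.24, 39.29, 54.68 MPa; alpha = -3.41, -0.66, -6.48) gives
mu0 = -32.86 MPa under the classical form — not a stable material — and
mu0 = +1.73 MPa under the solver form.  The package therefore defaults
to the solver convention and the constructor refuses any parameter set
whose mu0 is not positive.  The mu_n units are taken as MPa (consistent
with the mm-N-MPa system; the published set states no units — this is an
assumption, flagged in the config schema).

**Damage.** The impaired anterior wall is modelled as a proportional
stiffness loss: every mu_n is scaled by (1 - d), exponents untouched, so
the uniaxial stress at any stretch scales by exactly (1 - d).  The
default damaged state uses d = 0.5.  No damage evolution law is
implemented.

**Closed forms.** For incompressible uniaxial tension
(l, 1/sqrt(l), 1/sqrt(l)) the Cauchy stress is
`sigma = sum_n k_n (l^a_n - l^(-a_n/2))` with `k_n = mu_n` (classical)
or `2 mu_n/alpha_n` (solver); the nominal (engineering) stress is
`sigma/l`.  These closed forms are the oracles the finite-element bar
solutions are tested against.

## Thread geometry

A cog thread is a cylinder (presets: commercial 160 mm x 630 um,
computational 80 mm x 600 um) with wedge cuts of depth 200 um, axial
spacing 1600 um, in 4 radial directions at 90 deg, at blade angles
90/75/60/45 deg.  The wedge is bounded by the inclined leading face
(at the barb angle to the axis, axial extent depth/tan(angle)) and a
stop face normal to the axis, so all barbs open toward the same end.

Because the cut depth is below the filament radius, every cross-section
of the cut solid is star-shaped about the axis, and the solid is exactly
described by a radius function r(theta, y).  Geometry is therefore built
by lofting that radius function rather than by boolean subtraction —
watertight by construction, no robustness tolerances needed.  The two
nominally axis-normal faces (the stop face; the leading face at 90 deg)
are approximated by a short axial recovery ramp (`recovery_length`,
default 0.05 mm) so r stays single-valued in y; this perturbs the
removed volume slightly but not the minimum cross-section, which is what
the mechanics sees.

Volume meshing is structured: the cross-section disc (centre + rings) is
extruded station-by-station into prisms, each split into three
tetrahedra by the minimum-vertex-index rule (conforming across prisms),
then mid-edge nodes are inserted for 10-node quadratic tetrahedra.  No
external mesh generator is used; the price is that `tetrahedralize`
accepts only profile-backed surfaces, not arbitrary STL.  The polygonal
cross-section underestimates the circle area by about `6.6/n_theta^2`
(relative); at the default 48-64 circumferential segments this is
0.16-0.29%, which is the dominant bias in the virtual tensile test.

The minimum cross-section is computed by slicing the watertight surface
along its axis (exact axis for profile-backed meshes, principal axis of
the vertex cloud otherwise) with local refinement around the minimum.
With all four directions cut at the same axial stations (the default;
a per-direction phase is configurable), the deepest station of a
200 um / 600 um thread is the intersection of four chords — a
0.2 x 0.2 mm square core, 0.04 mm^2 — rather than a single
circle-minus-segment.  The minimum section depends on the cut depth
only, not the blade angle, which is the geometric root of the observed
angle-insensitivity of reinforcement.

## Finite-element core

Total-Lagrangian static solver on 10-node tetrahedra, 4-point Gauss
quadrature.

* **Ogden evaluation.** Eigen-decomposition of C = F^T F; isochoric
  split with volumetric penalty `U(J) = kappa/2 (J-1)^2`,
  `kappa = 1000 mu0` by default (quadratic tets tolerate this level of
  near-incompressibility without locking at the accuracy targeted
  here; the penalty gap is the ~0.1% discrepancy seen against the
  incompressible closed forms).  The spectral tangent uses analytic
  first/second derivatives of W in principal stretches and the
  divided-difference construction for the eigenprojection derivative,
  switching to the analytic limit when eigenvalues coincide within a
  1e-9 relative gap.  The tangent is verified against finite
  differences of the stress in the test suite.
* **Newton continuation.** Loads and prescribed displacements ramp
  proportionally; the first increment starts at 1/8 of the base step
  (failures are costlier than small steps), each success doubles the
  step back toward the base, and a failing step is bisected down to
  1/64 of the base before the solver returns a non-converged result
  with its residual history (never an exception).  A linear
  extrapolation predictor seeds each increment.  Newton steps are
  accepted with a bounded-growth rule (residual growth tolerated twice
  in a row, never more than 1000x, never non-finite) instead of a
  monotone line search: Newton residual norms are legitimately
  non-monotone near strongly nonlinear states, and demanding descent
  stalls the iteration.  A physical cap (5% of the mesh bounding-box
  diagonal) limits any single displacement update.  Convergence is
  declared at a relative residual of 1e-6 against the larger of the
  external and internal force norms.
* **Pressure.** Follower by default (integrated over the deformed
  surface with 3-point quadrature on quadratic facets); the follower
  load stiffness is omitted from the tangent — at the cough pressure
  (0.0157 MPa against mu0 = 1.73 MPa) the load-stiffness terms are
  ~1% of the material stiffness, costing a little convergence rate on
  pressure-driven problems and nothing on displacement-driven ones.
* **Contact.** Frictionless node-to-analytic-sphere penalty: a node
  penetrating by g feels `penalty * g` along the outward radial
  direction.  The default penalty is `10 mu0 h` (h = mean element
  edge): penetration stays below ~0.5% of the sphere travel while the
  Newton iteration remains stable when the active set changes.  (A
  100x penalty was tried first and makes the continuation diverge;
  the reaction force changes by less than the discretization error.)
* **Embedded threads.** In tissue scenarios a thread is a polyline of
  geometrically nonlinear axial (truss) segments with EA = thread
  modulus x minimum cut cross-section, tied to the host elements
  through the element interpolation at each path point (no relative
  motion — the kinematic reading of "full contact without relative
  motion").  Full 3-D thread meshes are reserved for the tensile
  scenario where the barb geometry itself is under study.  Segments
  are **tension-only** by default: a slender suture sheds compressive
  load by buckling, and a symmetric truss's negative geometric
  stiffness under compression would (unphysically) let reinforcement
  *soften* the indented wall; a ``carries_compression`` flag restores
  the symmetric truss where a strut is wanted.

## Scenarios

* **Virtual tensile test.** The (cut or uncut) thread is meshed in 3-D,
  one grip encastre, the other displaced axially to 1% strain by
  default.  Engineering stress uses the *uncut* nominal area
  pi d^2/4 for cut and uncut threads alike (standard suture-testing
  convention; keeps the curves comparable).  The crosshead speed of the
  physical protocol (10 mm/min) has no effect in a rate-independent
  static model and is metadata only.
* **Cough pressure.** Encastre at the canal base, antero-posterior and
  lateral restraint of the posterior sector (the rectum's support),
  uniform follower pressure (default 160 cmH2O = 0.0157 MPa, a
  worst-case cough) on the anterior wall facets.  Metric: maximum
  antero-posterior displacement over the anterior-wall nodes (mean
  reported alongside).
* **Ball burst.** A rigid analytic sphere (radius 10 mm) starts in
  tangent contact above the anterior side and moves supero-inferiorly
  (-y); reaction force is recorded against travel (default 5 mm in 25
  increments; both unreported in the source protocol and chosen for
  desk-scale convergence).
* **Angle study.** The cough scenario re-run per barb angle
  {90, 75, 60, 45} deg; angle enters only through EA via the minimum
  cross-section, which is angle-independent at fixed cut depth, so the
  computed spread is essentially zero — consistent with (and a
  geometric explanation of) the near-zero spread observed in the
  original simulations.

## Synthetic geometry — what it is and is not

The patient-specific pelvic model behind the published displacement
table is not distributed.  The stand-in is an idealized thick-walled
tube (defaults: length 80 mm, inner radius 15 mm, wall 3 mm —
order-of-magnitude anatomical choices), with the top 25% tapered into a
near-closed dome (residual 1 mm apex opening) standing in for the
uterus sitting atop the canal.  An open tube would present a
descending sphere with a bare rim edge — a near-singular contact the
real anatomy does not have.  The whole canal is inclined 45 deg from
the vertical (`tilt_deg`), reflecting the anatomical inclination of
the vagina: with the axis vertical, a supero-inferior indenter would
meet the wall end-on and the longitudinal threads nearly parallel to
its travel, a configuration in which tension-only threads cannot
resist; inclined, the sphere indents the anterior wall transversely —
the classic ball-burst, bowstring-engagement configuration — and
reinforcement raises the reaction force at every mesh resolution
tested.  Four longitudinal threads at mid-wall depth span the anterior
sector (the clinical insertion direction), following the dome taper up
to near the apex.

A green test on this geometry establishes orderings and signs —
damaged > healthy displacement, reinforced < damaged, reinforced burst
force >= bare, near-zero angle spread — **not** the published
millimetre values (7.489/7.857/7.071-7.078 mm) or the 13% burst-force
gain, all of which depend on the withheld anatomy.  The synthetic
burst gain at default settings is of the same sign and order (about
+7%).  Reinforcement engages progressively: at small sphere travel the
tissue absorbs the deformation and threads contribute little, so
ordering checks are run at travels of several millimetres.

The curve generator adds homoscedastic Gaussian noise (simplest
structure consistent with tensile-test scatter) to the exact closed
forms, seeded; real tensile data has heteroscedastic noise, toe-in
regions and slippage artifacts that fits against synthetic curves do
not exercise.

## Numerical defaults worth knowing

| parameter | default | why |
|---|---|---|
| Ogden convention | solver | only admissible form for the tissue set |
| kappa (penalty bulk) | 1000 mu0 | near-incompressibility vs conditioning |
| newton_tol | 1e-6 relative | reaction accuracy ~1e-5 mm on metrics |
| max Newton iterations | 25 | beyond this, bisecting the step is cheaper |
| step bisection floor | base/64 | then return non-converged + history |
| contact penalty | 10 mu0 h | penetration <0.5% of travel, stable active set |
| recovery_length | 0.05 mm | stop-face ramp; keeps loft single-valued |
| fit window (linear) | strain in [0, 0.02] | initial slope |
| Ogden fit | multi-start LM, seeded | non-convex in (mu_n, alpha_n) |
| tensile stress convention | uncut nominal area | suture-testing standard |

## Known limitations

* Isotropic tissue only; vaginal tissue is anisotropic.
* No viscoelasticity, no rate or temperature dependence, no fatigue.
* No tissue-tissue or self contact; sphere contact is frictionless.
* Embedded threads cannot debond, slide, or buckle.
* Structured meshing only (profile-backed solids and tubes); arbitrary
  surface tetrahedralization would need an external mesh generator.
* The displacement-only penalty formulation would lock for much
  stiffer volumetric penalties or linear tetrahedra; neither is used.
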