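# Methods

`bonedyn` couples three model layers into one deterministic workflow:

1. a **QCT-style material model** that converts a CT attenuation volume into
   per-node elastic properties of a tetrahedral femur mesh;
2. a **linear-elastic finite-element model** of the bone and its
   **Craig-Bampton superelement** reduction, which carries the stress
   analysis;
3. a **rigid planar neuro-musculoskeletal chain** with computed muscle
   control, whose femoral interface loads drive the superelement one-way.

This note documents the models, the defaults and their rationale, the
numerical choices, and what the bundled synthetic data can and cannot show.

## Material mapping

Attenuation (Hounsfield units) is converted to ash density through a linear
calibration, `rho_ash = slope * HU + intercept` (g/cm^3). If a density
phantom is present in the volume, the line is fit by ordinary least squares
over the insert means; otherwise the fixed default `rho_ash = HU / 895.93`
applies. Young's modulus follows the double-exponential law

    E = e0 * exp(a * exp(b * rho_ash)),   a = -5.19,  b = -2.30 cm^3/g,

clamped below at 1 MPa so air-like or negative densities never produce
non-physical stiffness. The prefactor `e0` is stored in pascals with a
default of 20 GPa (20 000 MPa): this puts `E(1 g/cm^3) ~ 11.9 GPa` and the
dense-bone asymptote at 20 GPa, consistent with cortical bone, whereas
interpreting the same coefficient in GPa would yield a 20 000 GPa asymptote.
The constant is an ordinary `MaterialLaw` field and can be overridden.

HU is sampled at node positions by trilinear interpolation (the natural
choice for a regular voxel lattice; point sampling and neighborhood
averaging differ only at the voxel scale). The element modulus used in
assembly is the arithmetic mean of the element's four nodal moduli. A
Poisson ratio of 0.3 and a mass density of 1940 kg/m^3 are applied
uniformly.

Elements are labelled cortical when their mean ash density reaches a
threshold (default 0.6 g/cm^3, configurable — dense cortical bone sits near
1.2-1.9 g/cm^3, trabecular bone well below). Mineral-loss scenarios scale
nodal moduli by class-specific factors — osteopenic (0.84 cortical / 0.67
trabecular) and osteoporotic (0.68 / 0.34) — with the node's class decided
by majority vote of its incident elements (tie goes to cortical) and the
1 MPa floor re-applied.

## Finite elements

Four-node linear (constant-strain) tetrahedra with a consistent mass
matrix. Quadratic 10-node decks are accepted by the reader and subdivided
into 8 conforming linear tetrahedra; the reduction and recovery algebra is
element-order-agnostic, and linear elements keep every verification oracle
(symbolic element matrix, patch test, analytic beams) exact and fast.
Bending accuracy is bought by refinement: the bundled cantilever
verification reaches the Timoshenko tip deflection within ~2% at the stated
fixture refinement (100 x 4 x 16 cells).

Reference-point couplings connect 6-DoF masters to node patches. Kinematic
couplings eliminate the patch DoFs (the patch moves rigidly with the
master); distributing couplings only spread an applied wrench as the
minimum-weighted-norm statically equivalent nodal force system, with
uniform weights by default. Interface masters, supports with prescribed
values, and a "support along a direction" constraint (used by the
sideways-fall protocol) are all expressed as sparse basis changes of the
generalized coordinates.

Transients use the Newmark constant-average-acceleration scheme
(beta = 1/4, gamma = 1/2, unconditionally stable, energy-conserving for
undamped linear systems), with loads interpolated linearly between samples.
Direct full-model transients damp with stiffness-proportional Rayleigh
damping matched to the target modal ratio at the first flexible frequency.
Unless a run starts genuinely at rest, transients start from static
equilibrium under the t = 0 load: sustained loads (gravity, standing
posture) would otherwise ring the structure's weakly damped modes and
pollute peak readouts.

Static solves use sparse LU with one round of iterative refinement — nodal
moduli span four orders of magnitude (1 MPa floor to ~18 GPa shell), and
refinement recovers the trailing digits that the reduction-exactness
guarantees rely on.

## Craig-Bampton superelement

The boundary set is the collection of 6-DoF interface masters (joints,
muscle attachments, via-points, strength-test points); everything else is
interior. The basis stacks static constraint modes `Psi = -K_ii^-1 K_ib`
with the lowest `n_modes` fixed-interface eigenmodes of `(K_ii, M_ii)`,
mass-orthonormalized (the eigensolver runs shift-inverted about zero with a
deterministic start vector; dense fallback for small interiors). Defaults:
30 retained modes, modal damping ratio 0.025 on every retained mode, the
boundary block undamped.

Two consequences are load-bearing for the pipeline and are tested:
static responses to interface loads are **exact** (constraint modes span
them), and reduced natural frequencies are Rayleigh-Ritz upper bounds that
decrease monotonically to the full-model values as modes are added.

Stress recovery operators `S_e = C_e B_e Phi_CB` are precomputed per
element at reduction time, so stresses and strains during a multibody
simulation cost one small matrix-vector product per element and time step —
the same trade of memory for runtime that makes the reduced route orders of
magnitude cheaper than direct transient FE.

## Musculoskeletal chain and control

The squat model is a sagittal-plane serial chain rooted at the ground-fixed
foot: shank, thigh, pelvis and torso connected by four hinges (ankle, knee,
hip, torso). The planar restriction mirrors the near-symmetry of a two-leg
squat; both legs are lumped into single segments (~67 kg subject total).
The thigh's joint-to-joint geometry and its muscle attachment landmarks are
taken from the toy femur itself, so the rigid chain and the flexible bone
share attachment sites exactly. Out-of-plane pelvis motion would be
restrained by a spring-damper symmetry condition; in the planar default it
is identically zero.

Dynamics come from a planar recursive Newton-Euler pass: the joint-space
mass matrix is built column-wise from unit accelerations, gravity and
Coriolis torques from the same recursion. Muscles are Hill-type line
actuators routed through segment-fixed via-points with
`force = C * a`, `C = PCSA * sigma_max`, and the force-length-velocity
factor fixed to 1. Moment arms come from tendon excursion
(`r = -ds/dbeta`, central differences at 1e-6 rad), which the tests verify
against the geometric lever-arm and attachment-Jacobian routes.

Muscle redundancy is resolved per control step by the volume-weighted
quadratic program `min a^T V a` subject to torque equality and activation
bounds, solved exactly by a primal active-set method (the diagonal Hessian
reduces each subproblem to a small augmented-KKT solve, iteratively refined
to keep the KKT residual near 1e-11). Reserve actuators — one ideal torque
per DoF with a quadratic weight of 1e3 x max(V) — guarantee feasibility and
are flagged whenever they exceed 1 N m; disabling them recovers hard
infeasibility (a phase-1 linear program then certifies feasibility or
raises).

The tracking controller feedback-linearizes the chain: desired acceleration
with critically damped error dynamics (`k_d = 2 sqrt(k_p)` per DoF,
`k_p = 400 s^-2` default, i.e. a 50 ms error time constant), inverse
dynamics for the net torques, the QP for activations, then fixed-step RK4
forward integration (control 100 Hz, integration 1 kHz) with zero-order-
hold activations; the muscle generalized torques and the mass matrix are
held over each 1 ms integration step while the gravity/Coriolis bias is
re-evaluated per stage. The error-feedback sign is chosen negative
(stabilizing), which is what produces the advertised critically damped,
non-overshooting error decay.

After the simulation, the femur free body is cut out: hip and knee
reactions follow from Newton-Euler balances of the subsystems beyond each
joint (so reserve torques, if any, appear in the interface moments), and
every femur-attached muscle force is applied at its attachment along its
current line of action. All wrenches are expressed in the femur body frame
(plane angles rotate +x toward +z, i.e. about -y of the right-handed 3D
frame) and transported to the superelement masters' reference points. For
the reduced transient the knee interface is clamped as the floating
reference, so recovered displacements are elastic deformation relative to
the distal femur.

## Strength test and risk readouts

The sideways-fall strength test fixes the distal interface, supports the
femoral head along the load line, and ramps a compressive load at the
greater trochanter directed toward the head centre. The deformation
measure is `|u_head - u_troch| / |x_head - x_troch|_0`; strength is the
load at which it reaches the failure threshold, default 0.04 (4%
deformation; a 4000-microstrain variant, 0.4%, is selectable through the
protocol since both conventions appear in the sideways-fall literature).
For the linear model the load-deformation curve is a line through the
origin, so strength follows exactly from the unit-load compliance; if the
configured ramp ends below the threshold the value is obtained by linear
extrapolation and a warning is raised (the bundled stubby toy femur is much
stiffer in this configuration than a real femur, so this is its normal
code path). Uniform stiffness scaling scales strength exactly linearly —
an invariant the acceptance tests check to 1e-10.

During the squat, the same head-trochanter measure is monitored from the
recovered superelement displacements, together with patch-averaged von
Mises stresses at four femoral-neck sites (superior/inferior in the bend
plane, anterior/posterior out of plane; 0.5 cm-scale element patches).
Computed strengths are placed against published cohort statistics of
sideways-fall femoral strength (non-fracture 5939 +/- 1919 N, fracture
3782 +/- 1563 N) as z-scores, with the label given by the nearer mean and
ties indeterminate.

## Synthetic study conditions

The fixture module defines the study conditions; all generators are pure
functions of parameters and seed.

* **Toy femur** — a swept solid (vertical shaft, smooth bend into a
  125-degree neck, spherical head, lateral trochanter bump) meshed by
  mapping a structured box onto disc cross-sections (area-preserving radial
  scaling, curvature-corrected; 6 tetrahedra per cell). Default resolution
  gives ~1400 nodes / ~6000 elements, and the mesh volume matches a dense
  quadrature of the analytic solid within 2%. Shaft radius 16 mm, cortical
  shell 4 mm, head radius 24 mm.
* **Attenuation volume** — voxelization of the same solid at 2.5 mm
  spacing: shell ~1500 HU (maps to ~18 GPa), trabecular core graded
  250-500 HU (so the core stays below the 0.6 g/cm^3 cortical threshold by
  construction), background -1000 HU, plus four phantom cylinders whose HU
  values invert exactly to their nominal densities (0.1-1.2 g/cm^3) through
  the default calibration; optional Gaussian noise (default sigma = 5 HU).
* **Squat trajectory** — the hip descends vertically above the fixed ankle
  with a raised-cosine height profile (cyclic, C^2, 4.5 s duration); ankle
  and knee angles follow from the closed two-link geometry with the trunk
  vertical, and time derivatives come from symbolically differentiated
  closed forms. Default depth is 15% of leg length (~80 degrees peak knee
  flexion, a moderate squat appropriate for a fragility-risk subject — and
  within the flexion range where via-point muscle routing keeps the knee
  extensor's moment arm physiological).
* **Muscle set** — eight synthetic line actuators, one antagonist pair per
  hinge, with capacities of 2.5-12 kN (PCSA x 0.5 MPa). The knee extensor
  runs through a two-point patellar channel (a condyle-level point and an
  anterior via-point) so its moment arm stays at the centimetre scale over
  the whole flexion range; the channel's mostly compressive contact force
  routes through the distal interface. With these defaults the squat runs
  without reserve-actuator activity and peak muscle forces stay in the
  physiological few-kN range.

What the synthetic data does **not** emulate: anatomical femur geometry
(anteversion, curvature, condyles), realistic trabecular architecture or
density gradients, imaging artifacts (beam hardening, partial volume,
metal), marker soft-tissue artifacts, wrapping muscle paths, ground
contact, or 3-D out-of-plane loading. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms under
controlled conditions — not clinical validity on real scans. In
particular, the toy femur's absolute strength in the sideways-fall
configuration (~100 kN) is far stiffer than a real femur's (~3-7 kN);
ratios and orderings across bone-quality scenarios are the meaningful
outputs.

## Numerical choices and degenerate inputs

* Tolerances: QP KKT residual ~1e-11 (iteratively refined direct solves);
  eigen-solves shift-inverted about zero; reduction static exactness holds
  to ~1e-11 relative on the mapped femur.
* Tie-breaks: node tissue class ties go to cortical; strength labels
  equidistant from both cohort means are indeterminate.
* Degenerate inputs raise early with context: inverted/degenerate elements
  name the offending element; empty coupling patches suggest a larger
  radius; coincident muscle path points, unreachable squat depths,
  non-monotone load histories, unknown configuration keys and phantom
  regressions with equal insert means are all rejected.
* Determinism: every random draw flows from the single configured seed;
  ARPACK eigen-solves use fixed start vectors; two runs of the full
  pipeline with the same seed produce byte-identical reports (timings are
  written to a separate profile file for this reason).

## Problem sizes

Default problem sizes were chosen so the whole toy workflow — fixture
generation, three material scenarios with assembly + reduction, a 4.5 s
squat under computed muscle control, two reduced transients and all
strength readouts — completes in well under a minute on one CPU, leaving
the full-model transient FE cross-validation (a ~4000-DoF direct Newmark
solve) as the most expensive single verification step.

## Known limitations

* Linear kinematics and linear elasticity throughout: no yield, fracture
  propagation, contact or geometric stiffening; the strength test reads a
  failure threshold off a linear load-deformation curve.
* One-way coupling: bone flexibility does not feed back into chain motion
  or muscle forces (appropriate while bone deformations stay small).
* The planar chain cannot produce out-of-plane femoral loading (torsion
  about the shaft, frontal-plane bending).
* Via-point muscle routing degrades beyond ~80 degrees of knee flexion;
  deep squats would need wrapping surfaces.
* The knee-clamped floating reference mixes a small amount of proximal
  rigid rotation into the head-trochanter measure; with the stated
  defaults this is the same effect a head-height deflection measurement
  would see in a bench test.
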