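# Methods

This note documents the models, algorithms and design choices behind
`gaitbench`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic fixtures do and do not show.

## Subject-specific multibody models

The whole body is modelled as a tree of rigid segments. The full model has
16 segments (pelvis, mid/upper trunk, head, and left/right upper arm,
forearm, hand, thigh, shank, foot) and 43 degrees of freedom: a 6-DoF
floating base on the pelvis, eleven 3-DoF joints (hips, ankles,
lumbosacral, xiphoid, shoulders, cervicale, wrists) and four 1-DoF joints
(knees, elbows). During walking the xiphoid and wrist joints barely move,
so the working model rigidly merges the upper trunk into the mid trunk and
each hand into its forearm — 13 segments, 34 DoF — using composite COMs and
parallel-axis inertia so total mass and momentum bookkeeping are unchanged.

Segment inertial parameters come from sex-specific regression tables
(adjusted Zatsiorsky–Seluyanov values as tabulated by de Leva) applied to
the subject's stature and body mass; the shipped table is versioned
(`gaitbench._deleva_data.TABLE_VERSION`) and pinned by tests. Mass
fractions are renormalised to sum to one. Thigh and shank lengths are
rescaled to match the measured hip-to-ankle leg length. A unilateral
prosthesis is modelled by scaling the three prosthesis-side leg segments by
one factor so the leg-mass ratio matches the measured value (e.g. 0.35);
per-segment overrides accept measured prosthesis parameters, and inertia
scaling can be disabled independently of mass scaling.

Joint-centre geometry (hip spacing, shoulder spacing, ankle height, foot
contact-point template with `heel`, `hallux`, `meta5`) is a documented
skeleton template scaled from stature — a convention of this package, not a
measured fact — and is user-overridable. Axis conventions: x anterior,
y left, z up; 3-DoF joints decompose intrinsically as Y (flexion),
X (ab/adduction), Z (rotation); the floating base is x-y-z translation
followed by yaw-pitch-roll. These conventions are likewise choices, fixed
and documented, because the underlying sources do not prescribe them.

## Contact dynamics and impacts

The equations of motion are evaluated in world coordinates: the mass
matrix is assembled from body Jacobians (`H = Σ Jᵀ M J`) and the bias
vector from the Newton–Euler equations at zero generalized acceleration.
This formulation trades a constant factor of speed for transparency; it is
validated against conservation laws and a null-space oracle in the tests.

Ground contact is a set of point constraints along declared world
directions (all three axes for spatial models; x and z for the planar
fixture, whose lateral direction carries no dynamics). Multiple points on
one flat foot make the raw constraint rows redundant; a deterministic
modified Gram–Schmidt sweep in declaration order keeps a well-conditioned
independent row subset (relative tolerance 0.02 — *nearly* dependent rows,
such as the fourth planar row of an almost-flat foot, are discarded too,
because retaining them makes the KKT solve ill-conditioned and the
contact-force split physically meaningless), so the KKT system

    [H Gᵀ; G 0] [a; −λ] = [τ − C; γ],   γ = −Ġ v

is uniquely solvable away from degenerate geometries. Touch-downs are
perfectly inelastic: `[H Gᵀ; G 0] [v⁺; −Λ] = [H v⁻; 0]` zeroes the
constrained point velocities, conserves the complementary momentum
projection and never increases kinetic energy. Integration uses fixed-step
RK4 with a post-step projection of (q, v) back onto the constraint manifold
(tolerance 1e-8) instead of Baumgarte stabilisation.

## Marker inverse kinematics

Per frame, virtual markers attached to segments are fitted to measured
positions by damped Gauss–Newton over the whole kinematic chain (constant
damping 1e-6, convergence `|Δq| < 1e-10`, at most 100 iterations), with
uniform marker weights by default and per-marker weights in configuration.
Frames with fewer than three valid markers are skipped; trajectories
warm-start each frame from the previous solution and report per-frame RMS
residuals (mean ± SD, the convention used for marker matching errors).
Missing markers are simply excluded — no marker-space interpolation.

## Multi-phase optimal-control reconstruction

A full stride beginning at left toe off is divided into 8 phases separated
by the events right heel off, left heel strike, left toe strike, right toe
off, left heel off, right heel strike, right toe strike, and ending at the
next left toe off. The four touch-downs are impact transitions; lift-offs
change the contact set continuously. The contact configuration per phase is
the natural one (flat stance → toe-only stance → double support with the
landing heel → double support with the landing foot flat, mirrored for the
other side); it is an interpretation of standard gait phases and is
configurable.

The reconstruction minimises the sum of squared differences between the
model's generalized coordinates (all of them, including the base) and the
inverse-kinematics reference, plus a control regularization
`γ_u ‖W u‖²` with `W = diag(w_l)`, `w_l = 1/100 (N m)⁻¹` by default and
`γ_u = 1e-3` (both configurable and echoed in outputs), and a small
contact-force regularizer of the same scale that resolves the
torque/contact-force indeterminacy of over-constrained double support
towards the minimum-norm solution. Transcription is direct collocation on
a per-phase node grid (target spacing 25 ms, at least two intervals per
phase; an explicit grid can be supplied). Two control parameterizations
are available behind the same interface: piecewise-linear controls with
Hermite–Simpson defects (default) and zero-order-hold controls with an
exactly matching fixed-step RK4 defect scheme — the latter pairs with
fixtures whose controllers are sampled on the same node clock, making the
ground truth an exact zero of the transcription. Defects, transition
conditions (position continuity, impact-map velocity jump) and
unilaterality hinge terms (negative vertical contact forces) enter the
least-squares residual with fixed weights rather than as hard constraints;
a dynamically consistent reference can zero them, and `check_solution`
independently re-integrates each collocation interval with the solved
controls and reports the local defects (whole-phase open-loop
re-integration is meaningless for an inherently unstable walker, whose
state error grows exponentially regardless of solution quality). An
optional weak velocity-consistency regularizer matches node velocities to
finite-differenced reference velocities. The nonlinear least-squares
problem is solved by a trust-region reflective method with sparse grouped
finite-difference Jacobians (central differences, Jacobian column scaling
and trust-region restarts configurable), warm-started from the reference
(velocities/accelerations by per-phase Savitzky–Golay differentiation that
never crosses an impact discontinuity; controls by least-squares inverse
dynamics per node, then refined by a cheap controls-only pre-solve with
the states frozen). Phase boundary times are fixed at the detected
events; stride periodicity is not imposed.

A structural identifiability limit of this inverse problem is worth
stating: torques applied during a short interval just before a touch-down
are nearly invisible in marker kinematics — their position effect is
second order in the interval length, and the impact map annihilates the
part of their velocity effect that lies along the newly constrained
directions. Recovering those controls therefore requires driving the
tracking residual to near machine precision, which with finite-difference
Jacobians converges too slowly to be practical; an NLP solver with
analytic derivatives would be the right tool. At the desk-scale problem
size the reconstruction reliably reaches a tracking term below 2e-3 rad²
and recovers torques to roughly 20% RMS, with the error concentrated in
the short toe-only and early double-support phases; trajectories, contact
forces, transition maps and all downstream stability metrics are
insensitive to this residual torque indeterminacy.

## Stability benchmarks

All benchmarks treat walking through the lens of the linear inverted
pendulum model (LIPM) with eigenfrequency `ω₀ = √(g/l)`:

* **Instantaneous Capture Point.** `r_icap = r_ref + ṙ_com/ω₀` in the
  ground plane. The reference point is the COM ground projection by
  default — with this choice, placing the CoP exactly on the ICaP brings
  the LIPM to rest, and the ICaP trajectory is smooth between the feet — or
  the CoP in the alternative "cop" mode. The mode is recorded in every
  output.
* **Normalized orbital energy.** `E'_lip = ½ ṙ'² − ½ (r'_com − r'_cop)² ω₀²`
  with every position-like quantity divided by the subject's leg length
  (hip to ankle) and the COM velocity assumed horizontal. ω₀ uses the
  instantaneous COM height by default ("com_height" mode); a constant
  leg-length mode is provided because the two roles — normalisation length
  and pendulum length — are conceptually distinct and the preferable pairing
  is not settled.
* **Residual orbital energy.** `E'_res` is `E'_lip` evaluated right after
  each heel strike, on the post-impact side of the transition (the first
  trajectory sample at or after the event when no impact map is
  available). Values are side-labelled; the stride average is the mean of
  the left-side and right-side values. Forward-progressing gait keeps
  `E'_res > 0`.
* **Angular-momentum decomposition.** Angular momentum about the
  instantaneous whole-body COM, split into upper body (trunk, head, arms)
  and lower body (pelvis and legs; the pelvis assignment is configurable),
  reported per plane with the convention frontal ↔ x component, sagittal ↔
  y, horizontal ↔ z. Upper + lower = full holds identically.
* **Foot placement.** At each heel strike the ICaP is expressed in the
  landing foot's frame: origin at the heel, anterior axis towards the
  hallux, medial axis towards the body midline (so left/right mirror into
  the same sign convention).

Gait events are detected from vertical contact-point forces (threshold 2%
body weight, 50 ms debounce against flicker) or, without force data, from
contact-point heights (below 5 mm, non-positive vertical velocity). The
CoP comes from force plates when available, otherwise from reconstructed
contact forces as the vertical-force-weighted average of the contact-point
positions.

## Synthetic fixtures

Two generators make every pipeline stage testable without recordings.

**Closed-form LIPM gait.** Piecewise `cosh/sinh` COM orbits with the CoP
fixed per support phase and instantaneous support exchange (optionally a
finite double support with linear CoP transfer). The periodic gait is
fully determined by COM height, step length L, step width W and step time
Ts: the sagittal orbit enters each phase L/2 behind the stance foot with
`ẋ₀ = ω₀ (L/2) coth(ω₀Ts/2)`, the lateral orbit is the mirror-symmetric
cosh arc with half-amplitude `W / (2 cosh(ω₀Ts/2))`. The default
conditions — COM height 0.9 m, L = 0.6 m, W = 0.2 m, Ts = 0.55 s, 10
steps — describe a normal adult pace. In `on_icap` mode the final step is
placed exactly on the COM-referenced ICaP, after which the COM decays to
rest — the defining capture property. The generator is deterministic; its
residual orbital energy has a closed form used as a test oracle.

**Forward-simulated planar walker.** A 7-segment sagittal walker (HAT,
thighs, shanks, feet; 9 DoF, 6 actuated) walks one full stride under a
task-space computed-torque controller: equality-constrained least squares
over accelerations, torques and contact forces with soft task targets
(base translation, trunk pitch, swing-ankle position and foot pitch,
heel-rise during toe-only stance and a smooth hyperextension barrier on
airborne knees). Touch-downs are geometric events resolved by the impact
map; lift-offs follow the designed schedule (heel off at 34% of each half
stride, toe off at 50%). Gait parameters (stride 1.0 s, step 0.40 m, hip
height 88% of leg length, base lead 84% of a step, landing pitch −0.12
rad) were chosen once for robust tracking with comfortably feasible
swing-leg geometry at a moderate walking speed and strictly unilateral
contact forces. For round-trip testing the controller runs through a
zero-order-hold sampler (20 ms node clock restarting at contact events)
and the contact ODE is integrated by plain 10 ms RK4 without constraint
projection, so the fixture's torques are exactly piecewise constant on a
known per-phase node grid and the trajectory is the exact composition of
the same integration map the reconstruction's "hold"/RK4 transcription
uses. The fixture's ground truth (states, torques, contact forces, exact
contact schedule) feeds the flagship round-trip test: synthesize markers →
IK → phase schedule → OCP.

What these fixtures do **not** emulate: soft-tissue artefact and marker
mislabeling, force-plate noise and filtering, compliant ground contact,
3-D balance (the walker is sagittal), muscle-level redundancy, and
within-subject stride variability. Passing tests therefore demonstrate the
correctness of the computational chain, not robustness to every artefact
of laboratory data.

## Numerical choices and problem sizes

* Dynamics oracles run on the 34-DoF model; integration tolerances: flight
  conservation to 1e-6 relative over 0.2 s at RK4 step 0.5 ms; constraint
  drift below 1e-8 via projection.
* The round-trip fixture uses a 100 Hz simulation of one 1.0 s stride,
  100 Hz synthetic markers, and a collocation grid of ≈ 50 intervals over
  8 phases — sizes chosen so the whole chain runs on a laptop-class single
  core in minutes while keeping the transcription exactly consistent with
  the fixture's integrator.
* Degenerate inputs: rank-deficient contact sets raise
  `DegenerateContactError`; fewer than three valid markers skip the frame;
  event sequences violating the stride grammar raise `ScheduleError`
  naming the offending event.

## Known limitations

* C3D files are not read (binary format); TRC and CSV are the supported
  input formats.
* The spatial 34-DoF model is exercised by the dynamics test suite but the
  reconstruction test fixture is the planar walker; the OCP code path is
  dimension-agnostic, and spatial problems simply cost more.
* The collocation enforces dynamics in a penalty sense; `check_solution`
  quantifies the residual physics violation of any returned solution.
* Marker gap-filling, functional calibration and soft-tissue compensation
  are out of scope; the IK consumes whatever markers are valid per frame.
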