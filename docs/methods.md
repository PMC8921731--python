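# Methods

`antkin` models the locomotor system of a walking ant as a tree of rigid
segments connected by idealised joints, estimates its joint-angle
trajectories from tracked anatomical landmarks, and quantifies how two
measurement uncertainties — marker placement and joint-geometry
identification — propagate into those angles.

## Joint geometry from articular surfaces

Ball-and-socket joints are reduced to a single point: the center of a sphere
fitted to the articular surface of the exoskeleton (µ-CT-derived point
clouds in practice, synthetic spherical caps in the test fixtures).  Hinge
joints are reduced to a line through the centers of two spheres fitted to
the joint's condyles.  The sphere fit is an algebraic linear least-squares
(Coope formulation: solve `[2p | 1][c; k] = |p|²`), which is exact on
noiseless data and gives a deterministic closed-form start, followed by one
Gauss–Newton polish of the geometric distances `| |p−c| − r |` (this matters
only for noisy partial caps; it is on by default and can be disabled).  A
cloud whose design matrix has a smallest singular value below 1e-9 of the
largest is rejected as coplanar.

Segment coordinate systems follow a fixed anatomical recipe.  The sagittal
plane is perpendicular to the line joining the two propodeal-spiracle sphere
centers and contains their midpoint.  The thorax frame sits at the midpoint
between the thorax/head and thorax/abdomen joint centers with y pointing
anteriorly; hinge frames sit at the axis midpoint with z along the axis
pointing medially and y toward the previous segment's origin; ball frames
sit at the sphere center with y pointing proximally.  Two constructions are
deliberately pinned down where the anatomical wording leaves a sign free:

* the lateral axis is `x = y × n_s` (`n_s` the sagittal normal), which makes
  `z = x × y` equal `+n_s` when y lies in the sagittal plane; a `flip_x`
  switch selects the mirrored convention;
* "pointing medially" is resolved by the sign of `z · (foot − origin)`,
  where `foot` is the frame origin's orthogonal projection onto the sagittal
  plane.  For a joint lying *on* the plane (the petiole) that dot product is
  identically zero, so the sign falls back to `z · n_s > 0`.

All frame constructions are orthonormal, right-handed to 1e-10, and
equivariant under a common rigid motion of their inputs (tested).

## The multibody model

Joints are typed: `free6` (floating base: three translations then three
intrinsic x–y–z rotations), `ball3` (intrinsic x–y–z Euler rotations, named
abduction / internal rotation / flexion), `hinge1` (rotation about the joint
z-axis; flexion is the negative direction), and `locked0`.  The intrinsic
x→y→z sequence matches the abduction / internal-rotation / flexion naming
order of the sign convention (abduction +x, internal rotation +y, extension
+z); the convention fixes signs but not a sequence, so the sequence choice
is documented here.  Coordinates are ordered by pre-order traversal of the
segment tree; angles are radians internally and degrees at every I/O
boundary.  Range-of-motion tables give one allowable span per DOF; spans are
centered on the reference pose, `[−R/2, +R/2]`, the least-informative
reading, and explicit min/max overrides are accepted in the model config.

Forward kinematics composes `T_child = T_parent · T(frame_in_parent) ·
T_joint(q) · T(frame_in_child)⁻¹`.  The marker Jacobian is geometric: a
rotational DOF with instantaneous world axis `a` through point `o`
contributes `a × (m − o)` to marker `m`; a translational DOF contributes its
world axis.  A numba-compiled kernel implements the same recursion as the
numpy reference path; a test pins both to 1e-12 agreement, and another
checks the Jacobian against central differences.

## Signal conditioning

Marker trajectories (C3D or TRC, normalised to mm) are low-pass filtered
with a fourth-order Butterworth at 5 Hz applied forward–backward
(zero-phase).  Zero-phase filtering is the standard choice in gait analysis
because phase lag would bias joint-angle timing; the documented side effect
is that the effective attenuation is the squared magnitude response.  Edges
use reflective padding of 3 × order samples.  Gaps of at most 10 frames are
linearly interpolated before filtering; channels with longer gaps keep their
missing flags and are excluded from IK.  Downsampling from the 300 Hz
acquisition rate to 100 Hz decimates exactly (every third sample);
non-integer ratios interpolate linearly.  Gait-cycle events (lift-off to
lift-off of the left middle leg) are supplied manually as frame indices;
automatic event detection is out of scope.

## Scaling and inverse kinematics

The model is scaled to the filmed specimen per segment: factor = mean over
frames of the experimental inter-marker distance divided by the model's
reference distance; segments without a measurable pair inherit the parent's
factor.  Scaling multiplies joint placement translations (by the parent's
factor), marker local positions and recorded geometry primitives; rotations
and ROM are untouched.

IK minimises the weighted sum of squared distances between observed and
model markers per frame, subject to ROM bounds, using a trust-region
reflective least-squares solver with the analytic Jacobian.  Defaults: equal
marker weights, relative cost tolerance 1e-10, step tolerance 1e-12, at
most 200 function evaluations per frame, 8 multi-starts at frame 0 (the
neutral pose with the floating base pre-aligned to the observed marker
centroid, plus seeded ROM-respecting offsets), warm starts afterwards.  The
reported RMSE is the weighted RMS over markers per frame, averaged
arithmetically over solved frames; a normalized RMSE divides by a supplied
body length.  With two markers per segment a segment's rotation about its
marker line is only resolved through chain coupling and ROM bounds, so the
solver flags frames whose Gauss–Newton Hessian has an eigenvalue ratio
below 1e-8 as weakly observable.

## Monte Carlo uncertainty propagation

Two studies, both with uniform draws inside a solid zone ("uniform
distribution over a spherical zone" is read as uniform over the ball, a
zone being a region):

* **Model markers** — every marker's local position is offset inside a ball
  of radius 0.4 mm (a representative camera-calibration residual at this
  scale), drawn once per iteration and held fixed over the trial: this
  models placement/identification error, not per-frame tracking noise.
* **Joint parameters** — ball centers are offset inside a 0.2 mm ball;
  hinge joints offset each of their two axis-defining condyle points inside
  an independent 0.2 mm ball, then the joint frame is rebuilt, perturbing
  both the location and the orientation of the axis while keeping it inside
  a 0.2 mm cylinder around the nominal axis.  The rebuilt hinge z-axis keeps
  the nominal orientation sign: re-deriving the medial sign from perturbed
  geometry flips the frame by 180° whenever the axis is nearly perpendicular
  to the medial direction, a configuration no re-identification of an
  articular surface would produce.

Each iteration re-solves the whole trial on a freshly perturbed model,
warm-started from the baseline (unperturbed) solution.  Iterations that
leave any frame unsolved are dropped and logged, never imputed.
Per-iteration substreams are spawned from a master seed, making the whole
pipeline a pure function of (inputs, seed); identical seeds give
bit-identical results.  Across iterations the per-DOF mean `θ̄(t)` and SD
`σ(t)` are formed; the coverage interval is `Δθ(t) = 2σ(t)`, interpreted as
the full band width (the published wording is ambiguous between full width
2σ and ±2σ; `coverage_multiplier` exposes the alternative and scales the
noise power by exactly that factor).

Sensitivity per DOF is the signal-to-noise ratio `SNR = Ps / Pn` with `Ps`
the peak-to-peak amplitude of `θ̄(t)` over the cycle and `Pn` the maximum
coverage interval.  DOFs with `Pn = 0` are excluded with a note rather than
reported as infinite; the floating-base coordinates are not part of the
joint-angle report.  Group averages are arithmetic means of per-DOF SNR
over: all joints, left/right leg joints, front/middle/rear leg joints, and
eight per-joint rows (thorax/head … metatarsus/tarsus); the petiole DOF
enters only the all-joints row.

Monte Carlo sweeps use a looser solver termination (relative cost tolerance
1e-6, step tolerance 1e-8): under mm-scale perturbation the residual
landscape has flat valleys where tightening costs hundreds of extra
iterations to move micro-degrees, orders below the coverage widths being
estimated.  Default iteration count is 1000; the test suite and the
acceptance script run 20–100 iterations on 5–8-frame gait slices, which is
sufficient for the degeneracy, determinism and radius-monotonicity
properties they check.

## The synthetic hexapod

The generator builds a fully known stand-in for the real animal: 40
segments, 65 DOF (6 floating base + 3 head + 1 petiole hinge + 3 abdomen +
two 10-DOF front legs + four 8-DOF middle/rear legs), two markers per
segment, ~6.6 mm body so that millimetre-scale uncertainty radii are
proportionate.  Leg topology: ball thorax/coxa; ball (front) or hinge
(middle/rear) coxa/trochanter — the blocked abduction/internal-rotation
DOFs of middle and rear coxa/trochanter joints and of the metatarsus reduce
those joints to hinges; hinge trochanter/femur, femur/tibia,
tibia/metatarsus, metatarsus/tarsus.  ROM spans use the published per-joint
allowable values; the petiole span (not published) defaults to 60°.
Condyle pairs are separated by 0.4 mm, matching the leg-joint width of an
ant this size.  Successive hinge axes are twisted about the leg direction
(30/−20/15/−15/10° at tro/fe/ti/mt/ta) because real leg joints do not share
one rotation plane — and parallel axes would make consecutive joints
mutually redundant under IK.  Markers sit at 30 % and 85 % of each segment
with 0.2 mm off-axis offsets in two different directions (about the cuticle
radius), which keeps every ball joint's axial rotation observable.

Gait trajectories are sums of a fundamental (one cycle per 1.39 s gait,
sampled at 100 Hz → 139 frames) and a 30 % second harmonic, amplitudes 35 %
of each half-span capped at 15° (leg hinges) / 8° (leg balls) / 5° (trunk),
opposite tripods in antiphase, the base advancing at 3.4 mm/s with a 0.1 mm
vertical bob.  Marker noise is optional (isotropic Gaussian or uniform
ball).  All generators are pure functions of (config, seed).

What the generator does *not* emulate: soft-tissue/cuticle deformation,
foot-slip and ground contact, correlated tracking errors, marker occlusion
patterns, and the model-vs-specimen mismatch that dominates real marker
residuals.  Passing recovery tests therefore demonstrate correctness of the
estimation machinery, not expected accuracy on real footage.

## Numerical choices and degenerate inputs

Sphere fits require ≥4 non-coplanar points; coincident condyle or spiracle
centers, a previous origin on a hinge axis, and proximal directions parallel
to the sagittal normal all raise degenerate-geometry errors.  ROM limits are
closed intervals (a value exactly at a limit is legal).  Perturbation draws
that collapse the two hinge points are resampled and counted.  Downsampling
refuses to upsample.  IK frames with fewer than `ceil(DOF/3)` usable markers
are flagged unsolved and excluded from averages.

## Known limitations

* On this synthetic geometry, joint-parameter zones of 0.2 mm produce
  coverage intervals comparable to or wider than 0.4 mm marker zones
  (median Pn ≈ 45–55° vs ≈ 33–40° on short gait slices): independent
  per-joint offsets distort the relative geometry of sub-millimetre
  segments at first order, and tilting a 0.4 mm condyle pair by up to
  arcsin(2·0.2/0.4) adds a further ~25 %.  Studies on real ant models have
  reported the opposite ordering (markers worse); the ordering is strongly
  geometry-dependent — it hinges on condyle separations, segment lengths and
  the perturbation realisation, which is why no test asserts a direction.
* The DOF budget (65) depends on treating the petiole as a 1-DOF hinge,
  which is a modelling choice, not an anatomical measurement.
* Scaling by inter-marker distance ratios and equal IK marker weights are
  assumptions; both are exposed as parameters for sensitivity testing.
* The C3D support covers the common Intel dialect with 3D point data only;
  analog channels are ignored.
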