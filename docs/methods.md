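# Methods

## Problem and scope

`gaitkin` implements a complete desk-testable version of a two-arm
marker-set comparison for inverse-kinematics (IK) gait analysis: the same
lower-limb rigid-body model is driven once by the standard 16-marker
Plugin protocol (P-model) and once by a 38-marker Redundant protocol
(R-model) on identical walking trials, and the resulting joint kinematics,
their scalar gait variables, and their intra-subject variability (MAV) are
compared within and between subject groups.  Because no human motion data
ship with the package, a synthetic gait generator with full ground truth
stands in for the laboratory; every processing stage is validated by
parameter recovery against that truth.

## Kinematic model

The skeleton is a tree of 9 rigid segments rooted at the pelvis (pelvis;
femur, shank, talus, foot per side) with 22 degrees of freedom:

| joint | DOF | axes (intrinsic order) |
|---|---|---|
| pelvis–lab | 3 T + 3 R | translation; axial rotation (Z), obliquity (X), tilt (−Y) |
| hip ×2 | 3 | flexion (−Y), adduction (∓X), internal rotation (±Z) |
| knee ×2 | 3 | flexion (+Y), adduction, rotation (as hip) |
| ankle ×2 | 1 | dorsiflexion (−Y) |
| subtalar ×2 | 1 | inversion (∓X) |

Lab frame: X = walking direction, Y = subject's left, Z = up; millimetres
and (at the API surface) degrees.  The zero pose is anatomical standing
with straight knees; all segment frames are lab-aligned there, each with
its origin at the segment's proximal joint centre.  Left-side
adduction/rotation/inversion axes are mirrored so that flexion, adduction,
internal rotation, dorsiflexion and inversion are positive on both sides.
The three-axis joints use the Cardan sequence flexion → adduction → axial
rotation (mediolateral, anteroposterior, longitudinal), the ISB-style
convention for the lower limb.  The talus is a massless connector of fixed
40 mm height whose only role is to separate the ankle and subtalar hinges.

Segment dimensions are four length parameters per side plus pelvic width
(nominal: pelvic width 240, thigh 410, shank 400, foot 250 mm).  Exact
numerical agreement with any specific commercial modelling system is not
claimed: such systems do not publish their internal coordinate
definitions, so the model here is a self-consistent implementation of the
same model class.

Marker attachment templates place each marker in its segment's frame with
the axial coordinate expressed as a *fraction of the segment length*
(e.g. KNE at 98 % of the thigh).  This matters twice: it makes segment
lengths observable from a single standing trial, and it guarantees that a
generator model and a calibration model agree at the true lengths.  The
redundant protocol lists 10 of its 11 extra markers per side explicitly;
the 11th is defined here as the medial malleolus (`ANK_M`), the natural
medial partner of `KNE_M`, and is isolated in one template row so it can
be swapped.  Offset validation bounds the *off-axis* (perpendicular to the
segment's long axis) distance at 200 mm — "on or near the segment
surface" — rather than the distance to the frame origin, which for a
distal marker on a 410 mm femur is necessarily larger.

## Calibration

Scaling follows the two-step order used in practice:

1. The standing frames are time-averaged per marker (visible frames only).
   Segment lengths and the static pose `q0` (29 parameters) are fitted
   jointly by trust-region nonlinear least squares to the averaged marker
   positions at nominal template attachments.  Bounds: lengths in
   [0.5, 1.5] × nominal, angles ±45°, pelvis position ±500 mm around the
   pelvis-marker centroid; tolerances 1e−12, deterministic (no random
   restarts).  A rank check on the final Jacobian rejects degenerate
   marker geometry (e.g. collinear markers).
2. Marker offsets are then *defined* as the segment-frame coordinates of
   each marker's mean standing position at `q0`, so the calibrated model
   reproduces the standing trial with zero residual by construction.

The P-model of a comparison study is always derived from the R-model
calibration by dropping the 22 extra markers, never calibrated separately;
shared markers therefore carry bit-identical offsets in both arms, and the
P-arm consumes bit-identical trial data minus exactly 22 columns.  This is
the controlled-comparison guarantee: any between-arm difference is
attributable to the marker set alone.

Per-side lengths are fitted independently (left–right asymmetry is real in
clinical populations), and lengths/pose are fitted before offsets rather
than simultaneously — fitting offsets jointly would make the problem
trivially solvable at any lengths.

## Inverse kinematics

Each frame solves `min_q Σ_i w_i ‖m_i_exp − m_i_model(q)‖²` over the
22-entry pose with a damped (Levenberg–Marquardt) least-squares solver and
the analytic kinematic Jacobian (`∂p/∂θ = ω × (p − c)` per rotational DOF).
Defaults: uniform weights (no published weighting exists for either
protocol), cost tolerance 1e−10 mm², at most 100 iterations per frame, no
joint limits.  Occluded markers are dropped from that frame's objective;
observability of the remainder is verified through the singular values of
the residual Jacobian, and an underdetermined frame either raises with the
weakly observed DOF names or (optionally) becomes a NaN gap.  Minimum
marker counts default to 12 (Plugin-sized sets) and 20 (Redundant-sized).

Trajectories are solved frame by frame, warm-started from the previous
frame (frame 0 from the calibration pose), which keeps angle histories
continuous and unwrapped.  Like all local marker-fitting IK, the solver
finds the correct minimum from a *neighbourhood* of the true pose; the
exact-recovery tests therefore initialize within ±15° of truth — two
orders of magnitude looser than the frame-to-frame motion at 100 Hz that
warm starting actually provides — over a ±60° working range.  Recovery
from an arbitrary cold start far outside that basin is not claimed (and is
not how the method is used).

## Gait processing

Right heel strikes are detected as local maxima of the heel marker's
anteroposterior position relative to the pelvis-marker centroid (the
standard coordinate-based rule; force-platform timing cannot be
synthesized meaningfully), with externally annotated events always taking
precedence.  A gait cycle is the interval between adjacent right heel
strikes.  Angles are resampled onto 101 points (0–100 % of the cycle) with
natural cubic splines, fitted on a finite-frame window two frames wider
than the cycle so an occlusion gap elsewhere in the trial cannot poison a
valid cycle; cycles containing gaps are excluded, not imputed.  From each
101-point curve the scalar variables are the angle at heel strike
(point 0), peak maximum, peak minimum and ROM (max − min).  MAV for one
angle and subject is the across-trial max-minus-min at each of the 101
points, averaged over the cycle; one trial gives 0 by definition.

## Statistics

Paired t-tests compare models and MAV on the same subjects; independent
t-tests (pooled or Welch) compare groups; Shapiro–Wilk (via
`scipy.stats.shapiro`, cross-checked against R's `shapiro.test`) screens
normality — failures are warned about but do not switch the analysis to
nonparametric tests, matching how such comparisons are conventionally
reported.  All tests are two-sided by default.  The point-wise comparison
runs a paired t-test at each of the 101 cycle points and reports the raw
(uncorrected) count of points with p < α, the convention for per-point
gait-curve reporting; Holm or Benjamini–Hochberg adjustment is available
via a flag for reuse outside that convention.  Zero-variance points are
reported as p = 1 when the two conditions agree there and p = 0 when they
differ by an exact constant.

A caution that the noiseless pipeline test makes concrete: a paired t-test
flags any *consistent* difference regardless of magnitude, including
solver-precision artifacts of order 1e−5 degrees.  Point counts should
always be read alongside the difference magnitudes.

The a-priori sample size for an independent two-sample t-test searches
increasing equal group sizes for noncentral-t power ≥ the target.  At
d = 1.37, α = 0.05, power 0.80 the one-tailed computation gives a total
N = 16 (8 per group, achieved power 0.831); the two-tailed variant gives
20.  The one-tailed default is used when reproducing that design because
it is the only tailedness consistent with N = 16 at those inputs; the
`tails` argument exposes both.

## Synthetic data generator

The generator emulates a 100 Hz optical-capture session.  Ground-truth
joint trajectories are truncated Fourier series in the stride phase
(mean + up to 4 harmonics per angle; left leg half a stride out of phase),
with the pelvis advancing at 1.2 m/s plus small periodic sway and bounce.
Default coefficients give hip flexion ≈ −10…30°, knee flexion ≈ 3…45°,
near-extended knees at heel strike — qualitatively normal level walking,
not a fit to any dataset.  Heel-strike ground truth is defined at the
stride boundaries of the parameterization, and the default coefficients
are phased (hip-flexion sine term −3.3°) so that the heel's anterior peak
— the event the detector looks for — coincides with those boundaries.
Default stride duration 1.1 s.

Marker corruption, applied to forward-kinematics positions of the truth
model:

* **soft-tissue artifact** — per-marker stride-periodic sinusoid with a
  random fixed direction and phase, amplitude scaled by segment (thigh
  1.0, shank 0.7, pelvis 0.5, foot 0.3 of the configured amplitude),
  reflecting the consistent finding that thigh markers move most relative
  to bone;
* white Gaussian noise per frame and axis;
* constant marker misplacement applied to walking trials only (a marker
  that shifted after the standing calibration);
* frame-range occlusion masks.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence`; identical seeds give bit-identical trials.

What the generator does **not** emulate: genuine STA is subject- and
task-specific with non-sinusoidal components; marker dropout in real labs
is burstier than fixed frame ranges; no ground-contact mechanics or
force-plate data exist, so kinetic validation is out of reach.  Passing
recovery tests therefore demonstrates correctness of the *algorithms*
under the stated noise model, not clinical accuracy on real skin-mounted
markers.

## Robustness experiment and study pipeline

`run_robustness_experiment` treats each seed as one synthetic subject:
calibrate the Redundant arm from a noisy standing trial (white σ 0.5 mm),
derive the Plugin arm, solve `n_trials` (default 3) noisy walking trials
with both arms on identical data, and record per-angle RMSE against truth
and across-trial MAV; summaries are medians and IQRs over seeds.  Under
5 mm stride-periodic STA with 20 seeds, the R-model's median RMSE and MAV
are below the P-model's for every reported right-leg angle — the synthetic
analogue of the redundant set's uniformly smaller intra-subject
variability, and the direction predicted by global least-squares fitting:
more markers average out artifact instead of letting single markers steer
a segment.

`run_pipeline` runs the full two-group study (default: 9 + 9 subjects,
3 trials each, 3 strides per trial, white σ 0.5 mm + STA 3 mm, one
injected group effect — reduced hip-flexion excursion in the patient
group).  Per-subject variation comes from resampled segment lengths
(CV 3 %), Fourier coefficients (CV 8 %) and stride duration (CV 3 %).
Subjects' trials are averaged before group statistics (the standard
choice); each trial contributes its first valid cycle.  The "three good
trials" convention is enforced as a minimum cycle count per subject
(default 3).

## Sizes, tolerances, numerical choices

* Test and experiment problem sizes (2–3 strides per trial, 20 seeds,
  100 k Monte-Carlo reps for power) were chosen as the smallest sizes at
  which the checked properties are stable and well-resolved.
* Exact-recovery tolerances: 1e−3° per angle for single-frame round trips,
  0.01° end-to-end, 1 mm on lengths, 1 frame (10 ms) on heel strikes.
* The TRC dialect is the tab-separated 5-line-header format; blank cells
  are occlusions, never zeros; metres are converted to millimetres on
  read.  C3D import is deliberately out of scope (binary format, not
  needed for any validation path).

## Known limitations

* The model omits muscles, inertia, joint-centre regression equations and
  any upper body; it is a kinematics-only artifact.
* No smoothing/filtering of solved angles (a Kalman or spline smoother
  would be a natural extension); warm starting provides continuity only.
* The point-wise comparison deliberately performs no multiplicity
  correction by default (see above).
* Coordinate-based event detection assumes overground-style walking with a
  clear anterior heel excursion; it will not handle pathological gait with
  absent heel excursion.
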