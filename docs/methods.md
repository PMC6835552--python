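# Methods

## Geometric model

The package reconstructs gaze in a device coordinate system (DCS) rigid to
the phone: origin at the display center, x along display rows, y along
columns toward the front camera, z out of the display toward the subject,
display plane z = 0, millimetres throughout. Angles cross the public API in
degrees and are converted to radians internally.

The optical axis is ω = (p − c)/‖p − c‖ from the cornea-curvature center c
to the pupil center p; estimating p and c from camera images is upstream of
this package and out of scope. The visual axis is fixed in an eye
coordinate system (ECS) with z_eye = ω: ν_ECS = (sin α cos β, sin β,
cos α cos β), where α and β are the subject's kappa offsets. The ECS basis
in the DCS is built from the device column axis,

    x₀ = normalize(ω × y_device),   y₀ = x₀ × ω,

and rolled about the optical axis by the R-Roll angle λ:
x(λ) = cos λ·x₀ + sin λ·y₀, y(λ) = −sin λ·x₀ + cos λ·y₀. Note the basis
written as matrix columns has determinant −1 in the frontal pose; this is
deliberate — it is the convention under which the rolled-frame route agrees
exactly with the classical added-offset parameterization
ν = (sin(θ+α) cos(φ+β), sin(φ+β), −cos(θ+α) cos(φ+β)) at zero pitch (the
two differ at second order elsewhere; a property test bounds the difference
by 0.05° for gaze and kappa angles within ±10°/±5°/±3°). The construction
is undefined when ω is parallel to y_device; that raises a typed error
rather than picking an arbitrary frame, because a silently wrong frame
corrupts the PoG.

The PoG is the ray–plane intersection c + t·ν with z = 0, t > 0. Off-screen
intersections are flagged, never clamped — the metrics layer decides what
to do with them.

## The roll-error law

If estimation assumes λ = 0 while the true roll is λ, the visual axis is
misdirected by δ with

    cos δ = cos λ + (1 − cos λ)·cos²α·cos²β.

The normative implementation (`delta_matrix`) applies the rolled and
unrolled ECS bases to ν_ECS and measures the angle between the images; the
closed form is validated against it to 1e-9° on a dense grid. Two numerical
choices matter: the matrix-path angle uses atan2(‖ν×ν₀‖, ν·ν₀) and the
closed form the half-angle identity sin(δ/2) = |sin(λ/2)|·√(sin²α cos²β +
sin²β), because the naive arccos of a near-unit dot product loses half the
floating-point mantissa near δ = 0. The angle between the rolled and
unrolled axes is independent of ω (the cross terms of the dot product
cancel), so the frontal-pose derivation applies at any gaze direction; on a
flat screen the *projected* error still grows slightly with target
eccentricity (≈ 0.15° at 8° eccentricity).

Useful corollaries: δ(λ) is even, zero at λ = 0, non-decreasing on
[0°, 180°], and quasi-linear with slope ≈ sin κ (κ = √(α²+β²)) over most of
the range; for small offsets δ ≈ √(2(1−cos λ))·κ within 2%.
`roll_sensitivity` differentiates δ by central difference with ±0.5° steps,
matching the "per degree of roll error" framing; 0.04°/° for the average
eye at λ = 90°.

## Subject calibration

`estimate_alpha_beta` fits (α, β) by nonlinear least squares
(scipy `least_squares`, trust-region reflective, bounds ±10°, tolerances
1e-10, initial guess (0, 0)) on the on-screen x/y residuals between each
frame's model PoG and its fixation target, with λ fixed to the calibration
roll (0 by default — calibration defines the roll reference). Residuals are
in screen millimetres, matching how fixation accuracy is reported, not in
visual angle. Frames whose PoG at the initial guess lies more than three
screen diagonals from the target are dropped as degenerate noise draws
before fitting; the count is reported. At least two distinct targets are
required (two unknowns). The problem is smooth and nearly linear in (α, β),
so convergence is immediate; permuting frame order perturbs the fit only at
the 1e-9° rounding level.

`PoGEstimator` exposes the same pipeline in scikit-learn form (`fit` =
calibration, `predict` = per-frame PoG, `score` = negative mean error in
mm) for composition with sklearn tooling.

## The simulator

`simulate_session` emulates the chin-rest validation protocol: the cornea
center fixed at (0, 0, 300 mm) (configurable offset), five fixation targets
(center plus (±38, ±21) mm on a 110 × 62 mm panel — a 5-inch-class display;
exact panel and target coordinates are a package choice), 150 frames
(5 s at 30 Hz) per target, device rolls {0°, 45°, 90°}. For each roll and
target the true optical axis is solved by fixed-point iteration so the
subject's visual axis lands exactly on the target (verified through the
forward model to < 1e-6 mm), and the pupil center is placed d_pc = 4 mm
along it — d_pc is not critical since the axis direction renormalizes; it
only scales feature-noise sensitivity.

Noise model, chosen for simplicity and calibrated once: i.i.d. Gaussian
perturbations (σ = 0.05 mm default) on every component of p and c, and
Gaussian noise (σ = 0.5° default) on the tracker's roll reading. 0.05 mm at
a 4 mm pupil–cornea separation produces ≈ 1.3° mean radial error at 300 mm,
the baseline accuracy class of mobile infrared trackers. The effective roll
optionally includes ocular counter-roll with linear gain ≤ 0.1 of head tilt
with respect to gravity; the head tracker reading deliberately excludes it,
since a real tracker measures only the head-to-device angle. One seeded
generator drives the whole session; the same seed reproduces the session
CSV byte for byte.

What the simulator does **not** model: camera projection and glint
synthesis, fixational eye movements, saccades and blinks, gaze-dependent
torsion (Listing's law), eyelid occlusion, or correlated feature errors
from image processing. Passing tests therefore demonstrate the correctness
and internal consistency of the geometry, the roll-error law, and the
calibration/evaluation pipeline — not the image-processing performance of
any physical tracker.

## Evaluation

Per-frame PoG estimates are computed with λ = 0 (Method 1) or the measured
roll (Method 2); frames whose geometry degenerates are flagged invalid and
excluded, never interpolated. Errors follow the study definition: per
target, the mean absolute on-screen distance; per roll, the unweighted mean
over targets; overall, the mean over rolls. Degree values convert the mm
aggregate through the nominal 300 mm viewing distance (the chin rest keeps
the true distance essentially constant; per-frame conversion differs by
< 0.02°). The 95% enclosing radius uses the linear-interpolation percentile
(≥ 20 frames required), and the distinct-target capacity uses a grid
packing with spacing equal to that radius — the simplest rule consistent
with 45 targets at the 12 mm compensated radius on a 110 × 62 mm panel; at
the 28 mm uncompensated radius it gives 6, so the rule (an interpretation,
the packing was never specified) is reported as a metric, not a claim.

Reference per-subject tables from the four-subject validation experiment
ship in `rollgaze.published` as inputs for the aggregate statistics. One
internal inconsistency is preserved and documented rather than patched: the
uncompensated 90° "Average" degree cell prints 3.50 while its per-subject
cells average 3.42 (the mm column is consistent); the package reproduces
column means.

## Problem sizes

Default test and acceptance runs use the full 2250-frame protocol for the
end-to-end pipeline, 10 seeded 750-frame sessions for calibration-recovery
statistics, and a 17 × 9 × 73 (α, β, λ) grid for the law-consistency check;
the whole suite completes in a few seconds on one core.
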