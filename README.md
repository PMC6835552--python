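# rollgaze

Model-based point-of-gaze (PoG) estimation for hand-held devices, with
compensation for the relative roll between the device and the eye.

## The problem

Remote infrared eye trackers estimate where a person looks by reconstructing
the eye's **optical axis** ω — the line through the center of corneal
curvature **c** and the pupil center **p** — and tilting it by the
subject-specific **kappa offsets** (α horizontal, β vertical) to get the
**visual axis** ν, whose intersection with the display plane is the PoG.
Desktop trackers assume the roll angle between the device and the eye is
fixed. A phone in the hand rolls freely: flipping from landscape to portrait
changes this **R-Roll** angle λ by 90°, and a model that ignores it projects
the kappa offsets into the wrong plane.

rollgaze implements the roll-aware model and everything needed to study it
without eye videos: the geometry, the analytic roll-error law, a forward
simulator of fixation sessions, kappa calibration, and the evaluation
harness comparing **Method 1** (assume λ = 0) against **Method 2** (use the
measured roll).

## The model

With c, p in device coordinates (origin at the display center, z toward the
subject, display plane z = 0):

* ω = (p − c)/‖p − c‖.
* Eye frame in device coordinates: z_eye = ω,
  x_eye(λ=0) = (ω × y_device)/‖ω × y_device‖, y_eye = x_eye × z_eye, and the
  roll mixes x/y: x_eye(λ) = cos λ·x₀ + sin λ·y₀, y_eye(λ) = −sin λ·x₀ + cos λ·y₀.
* Visual axis in the eye frame: ν_ECS = (sin α cos β, sin β, cos α cos β);
  in device coordinates ν = [x_eye y_eye z_eye]·ν_ECS.
* PoG = c + t·ν with t chosen so the z component hits 0.

Ignoring a roll of λ misdirects the visual axis by

    cos δ = cos λ + (1 − cos λ)·cos²α·cos²β,

independent of where the eye points. For the average adult eye
(α = 3°, β = 1.5°) a 90° roll gives δ ≈ 4.7°, i.e. ≈ 2.5 cm on a display at
30 cm — while δ changes only ≈ 0.04° per degree of error in the measured λ,
so a noisy head tracker is good enough to compensate.

## Worked example

Simulate a calibration session (five targets, 150 frames each, 30 cm, roll
0°), calibrate, then evaluate a three-roll session with both methods:

```python
import rollgaze as rg

truth = rg.SubjectEyeParams(alpha_deg=3.0, beta_deg=1.5)

cal = rg.simulate_session(truth, rolls_deg=[0.0], noise=rg.NoiseConfig(seed=2))
fit = rg.estimate_alpha_beta(cal)

test = rg.simulate_session(truth, noise=rg.NoiseConfig(seed=1))
for method in (1, 2):
    rep = rg.error_report(test, fit.params, method)
```

This prints:

```
calibrated alpha = 3.029 deg, beta = 1.522 deg (rms residual 7.56 mm over 750 frames)
method 1: 0 deg: 1.29 deg, 45 deg: 2.86 deg, 90 deg: 4.95 deg
method 2: 0 deg: 1.29 deg, 45 deg: 1.30 deg, 90 deg: 1.26 deg
predicted roll error delta(3, 1.5, 90) = 4.74 deg = 24.9 mm at 30 cm
```

Calibration recovers the generating kappa offsets to ~0.03° at the default
(~1° baseline) feature noise. Without compensation (method 1) the error
grows with the roll angle — the 90° excess over the ~1.3° noise floor is the
predicted δ — while the roll-aware method 2 stays flat at the noise floor.

The same pipeline is scriptable:

```sh
rollgaze simulate --out session.csv
rollgaze calibrate --session session.csv --out params.json
rollgaze report --session session.csv --params params.json --method 2 --out report.csv
rollgaze delta-table            # predicted delta per subject at 45 and 90 deg
```

The fit/predict shape is also available as a scikit-learn estimator:
`rg.PoGEstimator(method=2).fit(cal).predict(test)` returns per-frame
(x, y) gaze coordinates in mm.

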