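# gaitkin

Marker-set comparison for inverse-kinematics gait analysis.

Clinical gait labs estimate lower-limb joint angles by fitting a linked
rigid-body model to optical marker trajectories — global-optimization
inverse kinematics (IK).  The choice of marker set changes the answer: the
standard 16-marker Plugin protocol tracks each leg with single markers that
soft-tissue artifact and misplacement can steer, while a 38-marker
Redundant protocol (the Plugin set plus 11 extra markers per side) lets the
least-squares fit average those errors out.  `gaitkin` implements the full
comparison machinery so the effect of that choice can be studied, on real
TRC files or on synthetic gait with known ground truth:

* a 22-DOF lower-extremity model (6-DOF pelvis, 2×3-DOF hips, 2×3-DOF
  knees, 2×1-DOF ankles, 2×1-DOF subtalar joints) with forward kinematics
  and analytic Jacobians;
* the Plugin (16) and Redundant (38 = 16 + 22) marker protocols and the
  reduction between them;
* standing-trial calibration — segment lengths and static pose by
  nonlinear least squares, then per-marker offsets that reproduce the
  standing data exactly;
* per-frame IK, `min_q Σ_i w_i ‖m_i − m_i(q)‖²`, with warm-started
  trajectory solving, occlusion handling and observability checks;
* gait-cycle processing: coordinate-based heel-strike detection, 101-point
  cycle normalization, scalar variables (initial angle, peaks, ROM) and
  the MAV intra-subject variability statistic
  `MAV = (1/101) Σ_k [max_trial x_k − min_trial x_k]`;
* the statistical layer: Shapiro–Wilk, paired and independent t-tests,
  per-cycle-point significance counting, and noncentral-t sample-size
  computation;
* a seeded synthetic gait generator (Fourier joint trajectories, forward
  kinematics, stride-periodic soft-tissue artifact, white noise,
  misplacement, occlusion) with retained ground truth.

See `docs/methods.md` for the model conventions, assumptions and design
choices.

## Worked example

```python
import numpy as np
from gaitkin import (build_model, redundant_marker_set, generate_standing,
                     generate_trial, calibrate, solve_trajectory, mav,
                     normalize_cycles, extract_variables, reduce_to_plugin,
                     NoiseConfig, GaitTrajectoryConfig, power_n_two_sample)

# a-priori sample size for the two-group study design
print("N =", power_n_two_sample(1.37, alpha=0.05, power=0.80, tails=1))

# one synthetic subject: calibrate Redundant, derive the Plugin arm
subject = build_model({"thigh_R": 430.0, "thigh_L": 425.0})
protocol = redundant_marker_set(subject)
standing = generate_standing(subject, protocol, NoiseConfig(white_sigma=0.5, seed=0))
cal_r = calibrate(standing, protocol)
cal_p = cal_r.reduce_to_plugin()
print("recovered thigh_R = %.2f mm" % cal_r.model.lengths["thigh_R"])

# three walking trials with 5 mm soft-tissue artifact, solved by both arms
curves = {"redundant": [], "plugin": []}
for seed in (1, 2, 3):
    trial = generate_trial(subject, protocol, GaitTrajectoryConfig(n_strides=2),
                           NoiseConfig(sta_amplitude=5.0, seed=seed))
    for name, cal, data in (("redundant", cal_r, trial.markers),
                            ("plugin", cal_p, reduce_to_plugin(trial.markers))):
        series = solve_trajectory(cal, data)
        cyc = normalize_cycles(series, trial.truth_events, angles=["knee_flexion_R"])
        curves[name].append(cyc[0]["knee_flexion_R"])

for name in ("redundant", "plugin"):
    v = extract_variables(np.mean(curves[name], axis=0))
    print("%9s: knee flexion ROM %.1f deg, MAV %.2f deg"
          % (name, v.rom, mav(curves[name])))
```

Output:

```
N = 16
recovered thigh_R = 430.01 mm
redundant: knee flexion ROM 36.4 deg, MAV 0.38 deg
   plugin: knee flexion ROM 35.3 deg, MAV 1.16 deg
```

The calibration recovers the subject's thigh length to 0.01 mm from a
noisy standing trial; both marker sets report similar knee-flexion range
of motion, but the redundant set's across-trial variability (MAV) is about
a third of the plugin set's — redundancy averages the artifact out instead
of letting single markers steer the femur.

A full two-group study (two marker-set arms on identical data, per-variable
tables, per-point significance counts, MAV comparison) runs from a YAML
config via `gaitkin.pipeline.run_pipeline` or the CLI:

```sh
gaitkin simulate --config sim.yaml --out trials/
gaitkin calibrate --standing trials/standing.trc --protocol redundant --out model.yaml
gaitkin ik --model model.yaml --trial trials/walk01.trc --out angles.csv
gaitkin gait-stats --angles angles.csv --events trials/events_01.csv --out-dir stats/
gaitkin pipeline --config study.yaml --out report/
```

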