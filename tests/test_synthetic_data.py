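"""Synthetic gait generator: determinism, noise model, truth recovery."""

import numpy as np

from gaitkin import kinematic_model as km
from gaitkin import marker_protocol as mp
from gaitkin import synthetic_data as sd
from gaitkin.ik_solver import IKConfig, solve_trajectory


class TestTrajectories:
    def test_frame_and_event_counts(self):
        cfg = sd.GaitTrajectoryConfig(stride_duration=1.1, n_strides=3)
        series, events = sd.default_gait_trajectories(cfg)
        assert len(series.times) == 330
        assert len(events) == 4
        np.testing.assert_allclose(events, [0.0, 1.1, 2.2, 3.3])

    def test_zero_fourier_is_static_pose_with_forward_motion(self):
        cfg = sd.GaitTrajectoryConfig(fourier={}, n_strides=2)
        series, _ = sd.default_gait_trajectories(cfg)
        assert np.all(series.q[:, 6:] == 0.0)  # no joint motion
        # pelvis advances monotonically
        assert np.all(np.diff(series.q[:, 0]) > 0)

    def test_stride_periodicity(self):
        cfg = sd.GaitTrajectoryConfig(stride_duration=1.0, n_strides=3,
                                      sample_rate=100.0)
        series, _ = sd.default_gait_trajectories(cfg)
        angles = series.q[:, 3:]  # everything but pelvis translation
        np.testing.assert_allclose(angles[:100], angles[100:200], atol=1e-9)

    def test_left_leg_runs_half_stride_out_of_phase(self):
        cfg = sd.GaitTrajectoryConfig(stride_duration=1.0, n_strides=2)
        series, _ = sd.default_gait_trajectories(cfg)
        r = series.angle("hip_flexion_R")
        left = series.angle("hip_flexion_L")
        np.testing.assert_allclose(left[:50], r[50:100], atol=1e-9)


class TestStanding:
    def test_zero_noise_frames_equal_fk(self, truth_model):
        proto = mp.redundant_marker_set(truth_model)
        standing = sd.generate_standing(truth_model, proto, seed=7, n_frames=10)
        assert np.all(standing.frames.positions[0] == standing.frames.positions[5])
        q0 = km.zero_pose()
        q0[2] = (truth_model.lengths["thigh_R"] + truth_model.lengths["shank_R"]
                 + km.TALUS_HEIGHT)
        atts = mp.redundant_marker_set(truth_model).markers
        fk = km.predict_markers_array(truth_model, atts, q0)
        np.testing.assert_allclose(standing.frames.positions[0], fk, atol=1e-12)

    def test_white_noise_sd_near_nominal(self, truth_model):
        proto = mp.redundant_marker_set(truth_model)
        standing = sd.generate_standing(
            truth_model, proto, sd.NoiseConfig(white_sigma=2.0, seed=1),
            n_frames=300)
        sds = standing.frames.positions.std(axis=0)  # (M, 3) per-marker SDs
        assert abs(sds.mean() - 2.0) / 2.0 < 0.2

    def test_same_seed_bit_identical(self, truth_model):
        proto = mp.redundant_marker_set(truth_model)
        cfgs = [sd.NoiseConfig(white_sigma=1.5, seed=42) for _ in range(2)]
        a = sd.generate_standing(truth_model, proto, cfgs[0])
        b = sd.generate_standing(truth_model, proto, cfgs[1])
        np.testing.assert_array_equal(a.frames.positions, b.frames.positions)


class TestTrials:
    def test_same_seed_bit_identical(self, truth_model):
        proto = mp.redundant_marker_set(truth_model)
        cfg = sd.GaitTrajectoryConfig(n_strides=1)
        a = sd.generate_trial(truth_model, proto, cfg,
                              sd.NoiseConfig(white_sigma=1.0, sta_amplitude=4.0, seed=9))
        b = sd.generate_trial(truth_model, proto, cfg,
                              sd.NoiseConfig(white_sigma=1.0, sta_amplitude=4.0, seed=9))
        np.testing.assert_array_equal(a.markers.positions, b.markers.positions)

    def test_misplacement_shifts_marker_constantly(self, truth_model):
        proto = mp.redundant_marker_set(truth_model)
        cfg = sd.GaitTrajectoryConfig(n_strides=1)
        clean = sd.generate_trial(truth_model, proto, cfg, sd.NoiseConfig(seed=3))
        shifted = sd.generate_trial(
            truth_model, proto, cfg,
            sd.NoiseConfig(seed=3, misplacement={"RTHI": np.array([5.0, 0.0, 0.0])}))
        j = clean.markers.index("RTHI")
        np.testing.assert_allclose(
            shifted.markers.positions[:, j] - clean.markers.positions[:, j],
            np.tile([5.0, 0.0, 0.0], (clean.markers.n_frames, 1)), atol=1e-12)
        other = clean.markers.index("LHEE")
        np.testing.assert_array_equal(shifted.markers.positions[:, other],
                                      clean.markers.positions[:, other])

    def test_occlusion_tolerated_by_redundant_set(self, truth_model, calibrated):
        proto = mp.redundant_marker_set(truth_model)
        trial = sd.generate_trial(
            truth_model, proto, sd.GaitTrajectoryConfig(n_strides=1),
            sd.NoiseConfig(seed=2, occlusion_segments=[("LTHI", (50, 80))]))
        series = solve_trajectory(calibrated, trial.markers)
        err = np.abs(series.q[:, 3:] - trial.truth_angles.q[:, 3:]).max()
        assert err < 0.01  # noiseless: full recovery despite the gap

    def test_plugin_set_loses_accuracy_under_occluded_noisy_thigh(self, truth_model,
                                                                  calibrated):
        proto = mp.redundant_marker_set(truth_model)
        noise = sd.NoiseConfig(seed=4, white_sigma=2.0,
                               occlusion_segments=[("LTHI", (20, 90))])
        trial = sd.generate_trial(truth_model, proto,
                                  sd.GaitTrajectoryConfig(n_strides=1), noise)
        cal_p = calibrated.reduce_to_plugin()
        series_r = solve_trajectory(calibrated, trial.markers,
                                    IKConfig(min_markers_per_solve=12))
        series_p = solve_trajectory(cal_p, mp.reduce_to_plugin(trial.markers),
                                    IKConfig(min_markers_per_solve=10))
        truth = trial.truth_angles.angle("hip_rotation_L")
        err_r = np.sqrt(np.mean((series_r.angle("hip_rotation_L") - truth) ** 2))
        err_p = np.sqrt(np.mean((series_p.angle("hip_rotation_L") - truth) ** 2))
        assert err_r < err_p


class TestRobustnessExperiment:
    def test_zero_noise_scenario_exact_for_both_protocols(self):
        scen = sd.Scenario("clean", sd.NoiseConfig(),
                           sd.GaitTrajectoryConfig(n_strides=2))
        tab = sd.run_robustness_experiment([scen], n_seeds=1, n_trials=2,
                                           base_seed=0, standing_sigma=0.0)
        assert set(tab.protocol) == {"redundant", "plugin"}
        assert (tab.rmse_deg < 0.01).all()

    def test_summary_shape(self):
        scen = sd.Scenario("clean", sd.NoiseConfig(),
                           sd.GaitTrajectoryConfig(n_strides=2))
        tab = sd.run_robustness_experiment([scen], n_seeds=1, n_trials=2,
                                           base_seed=0, standing_sigma=0.0)
        summ = sd.summarize_robustness(tab)
        assert {"rmse_median", "mav_median"} <= set(summ.columns)
        assert len(summ) == 2 * len(sd.RIGHT_LEG_ANGLES)
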