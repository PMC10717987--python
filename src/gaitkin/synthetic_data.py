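"""Synthetic gait generator with known ground truth.

Emulates the data a marker-based gait lab produces — a standing reference
trial and repeated level-walking trials captured at 100 Hz — by driving the
scaled rigid-body model with smooth stride-periodic joint-angle
trajectories (truncated Fourier series per angle) and corrupting the
forward-kinematics marker positions with the error sources optical capture
actually suffers:

* *soft-tissue artifact* (STA): a stride-periodic per-marker sinusoid with
  random fixed direction and phase, largest on thigh markers;
* white measurement noise;
* constant marker *misplacement* applied after calibration (a marker that
  shifted between the standing trial and walking);
* frame-wise *occlusion* masks.

Ground-truth joint angles, heel-strike times and the generating model are
retained, so calibration, IK, gait processing and the statistics can all be
validated by parameter recovery.  Right heel strikes are defined at the
stride boundaries of the trajectory parameterization; the default Fourier
coefficients are phased so that the heel's peak anterior position (the
coordinate-based detection rule) coincides with those boundaries.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinematic_model as km
from . import marker_protocol as mp
from .calibration import CalibratedModel, StandingTrial, calibrate
from .exceptions import InvalidParameterError
from .gait_processing import GaitEvents, mav, normalize_cycles
from .ik_solver import IKConfig, JointAngleSeries, solve_trajectory
from .io import MarkerTrajectorySet

# ---------------------------------------------------------------------------
# Ground-truth joint trajectories
# ---------------------------------------------------------------------------

#: Per-angle Fourier coefficients (deg): mean, then (cos, sin) pairs per
#: stride harmonic.  Right-leg values; the left leg runs half a stride out
#: of phase.  Shapes and ranges qualitatively follow normal level walking
#: (hip flexion about -10..30 deg, knee flexion about 0..45 deg, heel-strike
#: posture near extension).
DEFAULT_GAIT_FOURIER: dict[str, tuple[float, ...]] = {
    "hip_flexion": (10.0, 20.0, -3.3),  # peak just before heel strike
    "hip_adduction": (2.0, 3.0, 2.0),
    "hip_rotation": (0.0, 4.0, 3.0),
    "knee_flexion": (22.0, -15.0, -8.0, -4.0, 0.0),
    "knee_adduction": (1.0, 2.0, 0.0),
    "knee_rotation": (0.0, 3.0, -2.0),
    "ankle_dorsiflexion": (2.0, -5.0, -8.0),
    "subtalar_inversion": (0.0, 3.0, 2.0),
    "pelvis_rotation": (0.0, 0.0, 3.0),
    "pelvis_obliquity": (0.0, 0.0, 0.0, 2.0, 0.0),
    "pelvis_tilt": (3.0, 0.0, 0.0, 1.0, 0.0),
}

#: Soft-tissue-artifact amplitude factors by segment (thigh worst).
STA_SEGMENT_FACTORS = {"femur": 1.0, "shank": 0.7, "pelvis": 0.5,
                       "foot": 0.3, "talus": 0.3}


@dataclass
class GaitTrajectoryConfig:
    """Parameters of the ground-truth periodic gait trajectories."""

    stride_duration: float = 1.1          # s
    n_strides: int = 4
    sample_rate: float = 100.0            # Hz
    pelvis_speed: float = 1200.0          # mm/s forward
    fourier: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GAIT_FOURIER))

    def __post_init__(self):
        if self.stride_duration <= 0 or self.sample_rate <= 0 or self.n_strides < 1:
            raise InvalidParameterError("stride_duration, sample_rate and n_strides "
                                        "must be positive")


@dataclass
class NoiseConfig:
    """Marker corruption model; ``seed`` makes generation bit-reproducible."""

    white_sigma: float = 0.0              # mm, i.i.d. per frame/axis
    sta_amplitude: float = 0.0            # mm, stride-periodic, per marker
    misplacement: dict[str, np.ndarray] = field(default_factory=dict)
    occlusion_segments: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.white_sigma < 0 or self.sta_amplitude < 0:
            raise InvalidParameterError("noise amplitudes must be >= 0")


@dataclass
class SyntheticTrial:
    """A generated walking trial with its full ground truth."""

    markers: MarkerTrajectorySet
    truth_angles: JointAngleSeries
    truth_events: GaitEvents
    truth_model: km.ScaledModel


def _fourier_eval(coeffs: tuple[float, ...], phase: np.ndarray) -> np.ndarray:
    out = np.full_like(phase, coeffs[0])
    pairs = coeffs[1:]
    for h in range(len(pairs) // 2):
        out = (out + pairs[2 * h] * np.cos(2 * np.pi * (h + 1) * phase)
               + pairs[2 * h + 1] * np.sin(2 * np.pi * (h + 1) * phase))
    return out


def default_gait_trajectories(cfg: GaitTrajectoryConfig | None = None,
                              model: km.ScaledModel | None = None,
                              ) -> tuple[JointAngleSeries, np.ndarray]:
    """Ground-truth pose series and right heel-strike times.

    Trajectories are periodic with the stride; heel strikes sit at stride
    boundaries by construction.  The pelvis advances at constant forward
    speed with small periodic sway and vertical bounce.
    """
    cfg = cfg or GaitTrajectoryConfig()
    model = model or km.build_model()
    T = int(round(cfg.n_strides * cfg.stride_duration * cfg.sample_rate))
    times = np.arange(T) / cfg.sample_rate
    phase = times / cfg.stride_duration

    stand_height = (model.lengths["thigh_R"] + model.lengths["shank_R"]
                    + km.TALUS_HEIGHT)
    q = np.zeros((T, km.N_DOF))
    cols = {n: i for i, n in enumerate(km.Q_NAMES)}
    q[:, cols["pelvis_tx"]] = cfg.pelvis_speed * times + 10.0 * np.sin(4 * np.pi * phase)
    q[:, cols["pelvis_ty"]] = 15.0 * np.sin(2 * np.pi * phase)
    q[:, cols["pelvis_tz"]] = stand_height + 10.0 * np.cos(4 * np.pi * phase)
    for name in ("pelvis_rotation", "pelvis_obliquity", "pelvis_tilt"):
        if name in cfg.fourier:
            q[:, cols[name]] = _fourier_eval(cfg.fourier[name], phase)
    for base, coeffs in cfg.fourier.items():
        if base.startswith("pelvis"):
            continue
        q[:, cols[f"{base}_R"]] = _fourier_eval(coeffs, phase)
        q[:, cols[f"{base}_L"]] = _fourier_eval(coeffs, phase + 0.5)

    events = np.arange(cfg.n_strides + 1) * cfg.stride_duration
    return JointAngleSeries(times=times, q=q), events


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def generate_standing(truth_model: km.ScaledModel, protocol: mp.MarkerProtocol,
                      noise: NoiseConfig | None = None, seed: int | None = None,
                      n_frames: int = 100, q0: np.ndarray | None = None,
                      sample_rate: float = 100.0) -> StandingTrial:
    """A quiet-standing reference trial: FK at a static pose + white noise."""
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    if q0 is None:
        q0 = km.zero_pose()
        q0[2] = (truth_model.lengths["thigh_R"] + truth_model.lengths["shank_R"]
                 + km.TALUS_HEIGHT)
    atts = _truth_attachments(protocol, truth_model)
    base = km.predict_markers_array(truth_model, atts, q0)
    pos = np.broadcast_to(base, (n_frames, *base.shape)).copy()
    if noise.white_sigma > 0:
        pos += rng.normal(0.0, noise.white_sigma, size=pos.shape)
    times = np.arange(n_frames) / sample_rate
    traj = MarkerTrajectorySet(tuple(a.name for a in atts), times, pos,
                               np.ones((n_frames, len(atts)), bool), sample_rate)
    return StandingTrial(traj)


def _truth_attachments(protocol: mp.MarkerProtocol, model: km.ScaledModel):
    """Protocol attachments re-resolved at the truth model's lengths."""
    if protocol.name in (mp.PLUGIN, mp.REDUNDANT):
        return mp.get_protocol(protocol.name, model).markers
    return protocol.markers


def generate_trial(truth_model: km.ScaledModel, protocol: mp.MarkerProtocol,
                   traj_cfg: GaitTrajectoryConfig | None = None,
                   noise_cfg: NoiseConfig | None = None) -> SyntheticTrial:
    """A walking trial: FK of truth trajectories + STA + noise + occlusion."""
    traj_cfg = traj_cfg or GaitTrajectoryConfig()
    noise_cfg = noise_cfg or NoiseConfig()
    rng = np.random.default_rng(noise_cfg.seed)
    truth, event_times = default_gait_trajectories(traj_cfg, truth_model)
    atts = list(_truth_attachments(protocol, truth_model))
    names = tuple(a.name for a in atts)

    T = len(truth.times)
    pos = np.empty((T, len(atts), 3))
    for t in range(T):
        pos[t] = km.predict_markers_array(truth_model, atts, truth.q[t])

    if noise_cfg.sta_amplitude > 0:
        phase = truth.times / traj_cfg.stride_duration
        for j, att in enumerate(atts):
            amp = noise_cfg.sta_amplitude * STA_SEGMENT_FACTORS[att.segment.split("_")[0]]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            phi = rng.uniform(0, 2 * np.pi)
            pos[:, j] += np.outer(amp * np.sin(2 * np.pi * phase + phi), direction)
    if noise_cfg.white_sigma > 0:
        pos += rng.normal(0.0, noise_cfg.white_sigma, size=pos.shape)
    for name, offset in noise_cfg.misplacement.items():
        if name in names:
            pos[:, names.index(name)] += np.asarray(offset, dtype=float)

    vis = np.ones((T, len(atts)), dtype=bool)
    for name, (f0, f1) in noise_cfg.occlusion_segments:
        if name in names:
            vis[f0:f1 + 1, names.index(name)] = False

    markers = MarkerTrajectorySet(names, truth.times, pos, vis, traj_cfg.sample_rate)
    return SyntheticTrial(markers=markers, truth_angles=truth,
                          truth_events=GaitEvents(event_times, source="annotated"),
                          truth_model=truth_model)


# ---------------------------------------------------------------------------
# Robustness experiment: Redundant vs Plugin under controlled noise
# ---------------------------------------------------------------------------

#: The paper-style right-leg angles on which RMSE and MAV are reported.
RIGHT_LEG_ANGLES = ("hip_flexion_R", "hip_adduction_R", "hip_rotation_R",
                    "knee_flexion_R", "knee_adduction_R", "knee_rotation_R",
                    "ankle_dorsiflexion_R", "subtalar_inversion_R")


@dataclass
class Scenario:
    """One noise condition of the robustness experiment."""

    name: str
    noise: NoiseConfig
    traj: GaitTrajectoryConfig = field(default_factory=GaitTrajectoryConfig)


def _solve_arm(cal: CalibratedModel, trial_markers: MarkerTrajectorySet,
               truth: JointAngleSeries, events: GaitEvents):
    """IK one arm of one trial; per-angle RMSE vs truth + normalized curves."""
    series = solve_trajectory(cal, trial_markers, IKConfig())
    rmse = {a: float(np.sqrt(np.mean((series.angle(a) - truth.angle(a)) ** 2)))
            for a in RIGHT_LEG_ANGLES}
    curves = normalize_cycles(series, events, angles=list(RIGHT_LEG_ANGLES))
    return rmse, curves


def run_robustness_experiment(scenarios, n_seeds: int = 20, n_trials: int = 3,
                              base_seed: int = 0,
                              standing_sigma: float = 0.5) -> pd.DataFrame:
    """Calibrate -> IK -> RMSE/MAV per scenario x protocol x seed.

    Each seed plays the role of one synthetic subject: a standing trial
    (white noise ``standing_sigma``) is calibrated with the Redundant
    protocol, the Plugin arm is derived by marker reduction, and
    ``n_trials`` noisy walking trials are solved by both arms on identical
    data.  Returns a tidy frame with per-angle RMSE against ground truth
    (mean over trials) and across-trial MAV.
    """
    truth_model = km.build_model()
    redundant = mp.redundant_marker_set(truth_model)
    rows = []
    for scenario in scenarios:
        for s in range(n_seeds):
            scen_key = zlib.crc32(scenario.name.encode()) % (2 ** 31)
            seed_root = np.random.SeedSequence([base_seed, scen_key, s])
            child = seed_root.generate_state(n_trials + 1)
            standing = generate_standing(
                truth_model, redundant,
                NoiseConfig(white_sigma=standing_sigma, seed=int(child[0] % (2 ** 31))))
            cal_r = calibrate(standing, redundant)
            cal_p = cal_r.reduce_to_plugin()
            acc = {p: {a: [] for a in RIGHT_LEG_ANGLES} for p in (mp.REDUNDANT, mp.PLUGIN)}
            curves_acc = {p: {a: [] for a in RIGHT_LEG_ANGLES} for p in (mp.REDUNDANT, mp.PLUGIN)}
            for k in range(n_trials):
                noise = NoiseConfig(white_sigma=scenario.noise.white_sigma,
                                    sta_amplitude=scenario.noise.sta_amplitude,
                                    misplacement=scenario.noise.misplacement,
                                    occlusion_segments=scenario.noise.occlusion_segments,
                                    seed=int(child[k + 1] % (2 ** 31)))
                trial = generate_trial(truth_model, redundant, scenario.traj, noise)
                reduced = mp.reduce_to_plugin(trial.markers)
                for proto, cal, data in ((mp.REDUNDANT, cal_r, trial.markers),
                                         (mp.PLUGIN, cal_p, reduced)):
                    rmse, curves = _solve_arm(cal, data, trial.truth_angles,
                                              trial.truth_events)
                    for a in RIGHT_LEG_ANGLES:
                        acc[proto][a].append(rmse[a])
                        curves_acc[proto][a] += [c[a] for c in curves]
            for proto in (mp.REDUNDANT, mp.PLUGIN):
                for a in RIGHT_LEG_ANGLES:
                    rows.append({"scenario": scenario.name, "protocol": proto,
                                 "seed": s, "angle": a,
                                 "rmse_deg": float(np.mean(acc[proto][a])),
                                 "mav_deg": mav(curves_acc[proto][a])})
    return pd.DataFrame(rows)


def summarize_robustness(table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of RMSE and MAV per scenario x protocol x angle."""
    def iqr(x):
        return float(np.percentile(x, 75) - np.percentile(x, 25))
    return (table.groupby(["scenario", "protocol", "angle"])
            .agg(rmse_median=("rmse_deg", "median"), rmse_iqr=("rmse_deg", iqr),
                 mav_median=("mav_deg", "median"), mav_iqr=("mav_deg", iqr))
            .reset_index())
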