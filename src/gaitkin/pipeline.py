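"""The two-arm study pipeline: Redundant vs Plugin on identical trials.

Mirrors the design of a marker-set comparison study: each subject is
calibrated once from a standing trial with the 38-marker Redundant
protocol; the Plugin arm is derived from that calibration by dropping the
22 extra markers, so both arms share bit-identical marker offsets for the
16 common markers and the Plugin arm consumes bit-identical trial data
minus exactly 22 columns.  Both arms solve the same walking trials, gait
cycles are segmented at detected right heel strikes, curves are normalized
to 101 points, scalar kinematic variables and MAV are extracted, and the
statistical layer compares models (paired tests) and groups (independent
tests), including the per-point significance counts along the cycle.

Configuration is a YAML/dict with either a ``synthetic`` study block
(groups, subject counts, noise — data are generated on the fly with known
group effects) or a ``subjects`` list naming standing/walking TRC files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinematic_model as km
from . import marker_protocol as mp
from . import synthetic_data as sd
from .calibration import CalibratedModel, StandingTrial, calibrate
from .exceptions import GaitKinError, InvalidParameterError
from .gait_processing import (GaitEvents, detect_heel_strikes, extract_variables,
                              mav, normalize_cycles)
from .ik_solver import IKConfig, solve_trajectory
from .io import MarkerTrajectorySet, read_trc
from .stats_compare import (DEFAULT_ALPHA, independent_t, paired_t,
                            pointwise_compare)

ANGLES = sd.RIGHT_LEG_ANGLES
VARIABLES = ("initial_angle", "peak_max", "peak_min", "rom")
PELVIS_MARKERS = ("LASI", "RASI", "LPSI", "RPSI")

#: Default synthetic two-group study: sample sizes as in a 9 + 9 subject
#: comparison, three walking trials per subject, moderate soft-tissue
#: artifact, and a reduced hip-flexion excursion in the patient group as
#: the injected between-group effect.
DEFAULT_STUDY_CONFIG: dict = {
    "seed": 0,
    "alpha": DEFAULT_ALPHA,
    "min_cycles": 3,
    "synthetic": {
        "groups": {
            "healthy": {"n_subjects": 9, "fourier_overrides": {}},
            "oa": {"n_subjects": 9,
                   "fourier_overrides": {"hip_flexion": [8.0, 13.0, -2.1]}},
        },
        "n_trials": 3,
        "noise": {"white_sigma": 0.5, "sta_amplitude": 3.0},
        "trajectory": {"stride_duration": 1.1, "n_strides": 3},
        "subject_length_cv": 0.03,
        "subject_fourier_cv": 0.08,
    },
}


@dataclass
class SubjectResult:
    """Per-subject processed output for both model arms."""

    subject: str
    group: str
    curves: dict[str, dict[str, np.ndarray]]      # protocol -> angle -> mean curve
    variables: dict[str, dict[str, dict[str, float]]]  # protocol -> angle -> var -> value
    mav: dict[str, dict[str, float]]              # protocol -> angle -> MAV deg


# ---------------------------------------------------------------------------
# Per-subject processing
# ---------------------------------------------------------------------------

def _pelvis_proxy(trial: MarkerTrajectorySet) -> np.ndarray:
    cols = [trial.index(n) for n in PELVIS_MARKERS if n in trial.marker_names]
    if len(cols) < 3:
        raise GaitKinError("trial lacks pelvis markers for event detection")
    return trial.positions[:, cols].mean(axis=1)


def _events_for(trial: MarkerTrajectorySet, annotated=None) -> GaitEvents:
    return detect_heel_strikes(trial.times, trial.trajectory("RHEE"),
                               _pelvis_proxy(trial), annotated=annotated)


def process_subject(subject: str, group: str, standing: StandingTrial,
                    trials: list[MarkerTrajectorySet], min_cycles: int = 3,
                    annotated_events: list | None = None,
                    ik_config: IKConfig | None = None) -> SubjectResult:
    """Calibrate once (Redundant), derive the Plugin arm, solve all trials.

    From each trial the first valid cycle contributes one normalized curve
    per angle; a subject needs at least ``min_cycles`` curves.  Subject
    summaries are the across-trial mean curve, mean scalar variables and
    across-trial MAV, per model arm.
    """
    cal_r = calibrate(standing, mp.redundant_marker_set())
    cal_p = cal_r.reduce_to_plugin()
    arms: dict[str, tuple[CalibratedModel, bool]] = {
        mp.REDUNDANT: (cal_r, False), mp.PLUGIN: (cal_p, True)}

    all_curves: dict[str, dict[str, list[np.ndarray]]] = {
        p: {a: [] for a in ANGLES} for p in arms}
    for i, trial in enumerate(trials):
        annotated = annotated_events[i] if annotated_events else None
        events = _events_for(trial, annotated)
        for proto, (cal, reduce) in arms.items():
            data = mp.reduce_to_plugin(trial) if reduce else trial
            series = solve_trajectory(cal, data, ik_config)
            cycles = normalize_cycles(series, events, angles=list(ANGLES))
            if cycles:  # first valid cycle of the trial
                for a in ANGLES:
                    all_curves[proto][a].append(cycles[0][a])

    curves, variables, mavs = {}, {}, {}
    for proto in arms:
        n_curves = len(all_curves[proto][ANGLES[0]])
        if n_curves < min_cycles:
            raise GaitKinError(
                f"subject {subject}: only {n_curves} valid cycles for {proto} "
                f"arm (need >= {min_cycles})")
        curves[proto] = {a: np.mean(all_curves[proto][a], axis=0) for a in ANGLES}
        variables[proto] = {}
        for a in ANGLES:
            per_trial = [extract_variables(c) for c in all_curves[proto][a]]
            variables[proto][a] = {v: float(np.mean([getattr(k, v) for k in per_trial]))
                                   for v in VARIABLES}
        mavs[proto] = {a: mav(all_curves[proto][a]) for a in ANGLES}
    return SubjectResult(subject, group, curves, variables, mavs)


# ---------------------------------------------------------------------------
# Synthetic study generation
# ---------------------------------------------------------------------------

def _synthetic_subjects(cfg: dict, seed: int):
    """Yield (subject_id, group, standing, trials) with per-subject variation."""
    syn = cfg["synthetic"]
    noise = syn.get("noise", {})
    traj = syn.get("trajectory", {})
    len_cv = float(syn.get("subject_length_cv", 0.03))
    fou_cv = float(syn.get("subject_fourier_cv", 0.08))
    for group, gcfg in syn["groups"].items():
        overrides = {k: tuple(v) for k, v in gcfg.get("fourier_overrides", {}).items()}
        for j in range(int(gcfg["n_subjects"])):
            gkey = zlib.crc32(group.encode()) % (2 ** 31)
            ss = np.random.SeedSequence([seed, gkey, j])
            rng = np.random.default_rng(ss)
            lengths = {k: v * (1.0 + len_cv * rng.standard_normal())
                       for k, v in km.NOMINAL_LENGTHS.items()}
            model = km.build_model(lengths)
            fourier = dict(sd.DEFAULT_GAIT_FOURIER)
            fourier.update(overrides)
            fourier = {k: tuple(c * (1.0 + fou_cv * rng.standard_normal())
                                for c in v) for k, v in fourier.items()}
            tcfg = sd.GaitTrajectoryConfig(
                stride_duration=float(traj.get("stride_duration", 1.1))
                * (1.0 + 0.03 * rng.standard_normal()),
                n_strides=int(traj.get("n_strides", 3)),
                sample_rate=float(traj.get("sample_rate", 100.0)),
                fourier=fourier)
            proto = mp.redundant_marker_set(model)
            child = ss.generate_state(int(syn.get("n_trials", 3)) + 1)
            standing = sd.generate_standing(
                model, proto, sd.NoiseConfig(
                    white_sigma=float(noise.get("white_sigma", 0.5)),
                    seed=int(child[0] % (2 ** 31))))
            trials = []
            for k in range(int(syn.get("n_trials", 3))):
                ncfg = sd.NoiseConfig(
                    white_sigma=float(noise.get("white_sigma", 0.5)),
                    sta_amplitude=float(noise.get("sta_amplitude", 0.0)),
                    seed=int(child[k + 1] % (2 ** 31)))
                trials.append(sd.generate_trial(model, proto, tcfg, ncfg).markers)
            yield f"{group}_{j:02d}", group, standing, trials


def _file_subjects(cfg: dict):
    for entry in cfg["subjects"]:
        standing = StandingTrial(read_trc(entry["standing"]))
        trials = [read_trc(p) for p in entry["trials"]]
        yield str(entry["id"]), str(entry["group"]), standing, trials


# ---------------------------------------------------------------------------
# Statistics over processed subjects
# ---------------------------------------------------------------------------

def _group_tables(results: list[SubjectResult], alpha: float):
    groups = sorted({r.group for r in results})
    by_group = {g: [r for r in results if r.group == g] for g in groups}
    for g, rs in by_group.items():
        if len(rs) < 2:
            raise InvalidParameterError(
                f"group {g!r} has {len(rs)} subject(s); between-subject "
                "statistics need at least 2")

    var_rows, mav_rows, pw_rows, curve_rows = [], [], [], []
    for g, rs in by_group.items():
        for a in ANGLES:
            # between-model paired tests on scalar variables and MAV
            for v in VARIABLES:
                xr = np.array([r.variables[mp.REDUNDANT][a][v] for r in rs])
                xp = np.array([r.variables[mp.PLUGIN][a][v] for r in rs])
                try:
                    p = paired_t(xr, xp).p_value
                except InvalidParameterError:
                    p = np.nan
                var_rows.append({"group": g, "angle": a, "variable": v,
                                 "mean_R": xr.mean(), "sd_R": xr.std(ddof=1),
                                 "mean_P": xp.mean(), "sd_P": xp.std(ddof=1),
                                 "p_between_models": p})
            mr = np.array([r.mav[mp.REDUNDANT][a] for r in rs])
            mp_ = np.array([r.mav[mp.PLUGIN][a] for r in rs])
            try:
                p = paired_t(mr, mp_).p_value
            except InvalidParameterError:
                p = np.nan
            mav_rows.append({"group": g, "angle": a,
                             "mav_R_mean": mr.mean(), "mav_R_sd": mr.std(ddof=1),
                             "mav_P_mean": mp_.mean(), "mav_P_sd": mp_.std(ddof=1),
                             "p_between_models": p})
            # point-wise between-model comparison
            cr = {r.subject: r.curves[mp.REDUNDANT][a] for r in rs}
            cp = {r.subject: r.curves[mp.PLUGIN][a] for r in rs}
            pw = pointwise_compare(cr, cp, alpha=alpha)
            pw_rows.append({"group": g, "angle": a,
                            "n_significant_points": pw.n_significant_points,
                            **{f"p{k}": pw.p_values[k] for k in range(len(pw.p_values))}})
        for r in rs:
            for proto in (mp.REDUNDANT, mp.PLUGIN):
                for a in ANGLES:
                    for v in VARIABLES:
                        curve_rows.append({"subject": r.subject, "group": g,
                                           "model": proto, "angle": a, "variable": v,
                                           "value": r.variables[proto][a][v]})

    between_rows = []
    if len(groups) == 2:
        ga, gb = groups
        for proto in (mp.REDUNDANT, mp.PLUGIN):
            for a in ANGLES:
                for v in VARIABLES:
                    xa = np.array([r.variables[proto][a][v] for r in by_group[ga]])
                    xb = np.array([r.variables[proto][a][v] for r in by_group[gb]])
                    try:
                        p = independent_t(xa, xb).p_value
                    except InvalidParameterError:
                        p = np.nan
                    between_rows.append({"model": proto, "angle": a, "variable": v,
                                         f"mean_{ga}": xa.mean(), f"mean_{gb}": xb.mean(),
                                         "p_between_groups": p})
    return {"variables": pd.DataFrame(var_rows),
            "mav": pd.DataFrame(mav_rows),
            "pointwise": pd.DataFrame(pw_rows),
            "between_groups": pd.DataFrame(between_rows),
            "long": pd.DataFrame(curve_rows)}


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None,
                 ) -> dict[str, pd.DataFrame]:
    """Run the full two-arm comparison study described by ``config``.

    Returns the report tables and, when ``output_dir`` (or
    ``config['output_dir']``) is given, writes them as CSV files:
    ``variables.csv`` (per-variable means/SDs and between-model p),
    ``mav.csv``, ``pointwise.csv`` (per-point p values and significance
    counts), ``between_groups.csv`` and ``boxplot_long.csv``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    alpha = float(config.get("alpha", DEFAULT_ALPHA))
    min_cycles = int(config.get("min_cycles", 3))
    seed = int(config.get("seed", 0))

    if "synthetic" in config:
        subject_iter = _synthetic_subjects(config, seed)
    elif "subjects" in config:
        subject_iter = _file_subjects(config)
    else:
        raise InvalidParameterError("config needs a 'synthetic' or 'subjects' section")

    results = []
    for subject, group, standing, trials in subject_iter:
        try:
            results.append(process_subject(subject, group, standing, trials,
                                           min_cycles=min_cycles))
        except GaitKinError as exc:
            raise GaitKinError(f"subject {subject} ({group}): {exc}") from exc

    tables = _group_tables(results, alpha)
    out = output_dir or config.get("output_dir")
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        names = {"variables": "variables.csv", "mav": "mav.csv",
                 "pointwise": "pointwise.csv",
                 "between_groups": "between_groups.csv", "long": "boxplot_long.csv"}
        for key, fname in names.items():
            tables[key].to_csv(out / fname, index=False)
    return tables
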