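"""Gait events, cycle normalization, kinematic variables and MAV.

A gait cycle is the interval between adjacent right-leg heel strikes.
Joint-angle histories are time-normalized to 0-100 % of the cycle and
resampled with cubic-spline interpolation onto 101 points; from each
normalized curve the four standard scalar variables are extracted (angle at
heel strike, peak maximum, peak minimum, range of motion).  Intra-subject
variability across a subject's repeated trials is summarized by the MAV
(mean absolute variability): the across-trial max-minus-min at each of the
101 points, averaged over the cycle.

Heel strikes are detected with the coordinate-based rule — local maxima of
the heel marker's anteroposterior position relative to the pelvis — unless
externally annotated events are supplied, which always take precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .exceptions import GaitKinError
from .ik_solver import JointAngleSeries

N_CYCLE_POINTS = 101


@dataclass
class GaitEvents:
    """Right heel-strike times defining gait cycles."""

    right_heel_strike_times: np.ndarray
    source: str = "detected"  # detected | annotated

    def __post_init__(self):
        t = np.asarray(self.right_heel_strike_times, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise GaitKinError("heel-strike times must be strictly increasing")
        self.right_heel_strike_times = t

    @property
    def cycles(self) -> list[tuple[float, float]]:
        t = self.right_heel_strike_times
        return [(t[i], t[i + 1]) for i in range(len(t) - 1)]


@dataclass
class KinematicVariables:
    """Scalar gait variables of one normalized joint-angle curve (deg)."""

    initial_angle: float
    peak_max: float
    peak_min: float
    rom: float


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

_MIN_EXCURSION_MM = 5.0   # flat signals yield no events
_PEAK_PROMINENCE_FRACTION = 0.2


def detect_heel_strikes(times, heel_positions, pelvis_positions,
                        annotated=None) -> GaitEvents:
    """Coordinate-based heel-strike detection for the right leg.

    Events are the local maxima of the heel marker's anterior (X) position
    relative to the pelvis — the instant the foot is reached furthest
    forward.  Externally ``annotated`` event times pass through untouched.
    """
    if annotated is not None:
        return GaitEvents(np.asarray(annotated, dtype=float), source="annotated")
    times = np.asarray(times, dtype=float)
    signal = (np.asarray(heel_positions, dtype=float)[:, 0]
              - np.asarray(pelvis_positions, dtype=float)[:, 0])
    if np.ptp(signal) < _MIN_EXCURSION_MM:
        warnings.warn("heel shows no anteroposterior excursion; no events detected",
                      stacklevel=2)
        return GaitEvents(np.array([]))
    peaks, _ = find_peaks(signal, prominence=_PEAK_PROMINENCE_FRACTION * np.ptp(signal))
    if peaks.size == 0:
        warnings.warn("no heel-strike events found", stacklevel=2)
    return GaitEvents(times[peaks])


# ---------------------------------------------------------------------------
# Time normalization
# ---------------------------------------------------------------------------

def time_normalize(series: JointAngleSeries, cycle: tuple[float, float],
                   angles: list[str] | None = None) -> dict[str, np.ndarray]:
    """Resample each angle onto 101 points spanning one gait cycle.

    Natural cubic splines are fitted to the solved per-frame angles and
    evaluated at 0, 1, ..., 100 % of ``cycle = (t_heel_strike, t_next)``.
    """
    t0, t1 = float(cycle[0]), float(cycle[1])
    if not (t1 > t0):
        raise GaitKinError(f"empty cycle ({t0}, {t1})")
    if t0 < series.times[0] - 1e-9 or t1 > series.times[-1] + 1e-9:
        raise GaitKinError(f"cycle ({t0}, {t1}) outside solved time span "
                           f"[{series.times[0]}, {series.times[-1]}]")
    in_cycle = (series.times >= t0 - 1e-9) & (series.times <= t1 + 1e-9)
    if in_cycle.sum() < 4:
        raise GaitKinError("cycle spans fewer than 4 frames; cannot fit a cubic spline")
    dt = float(np.median(np.diff(series.times))) if len(series.times) > 1 else 0.0
    window = (series.times >= t0 - 2 * dt) & (series.times <= t1 + 2 * dt)
    grid = np.linspace(t0, t1, N_CYCLE_POINTS)
    out: dict[str, np.ndarray] = {}
    for name in (angles or series.names):
        y = series.angle(name)
        if np.any(~np.isfinite(y[in_cycle])):
            raise GaitKinError(f"angle {name!r} contains gaps inside the cycle")
        use = window & np.isfinite(y)
        spline = CubicSpline(series.times[use], y[use], bc_type="natural")
        out[name] = spline(grid)
    return out


def normalize_cycles(series: JointAngleSeries, events: GaitEvents,
                     angles: list[str] | None = None,
                     skip_gapped: bool = True) -> list[dict[str, np.ndarray]]:
    """Normalized curves for every complete cycle in a trial.

    Cycles whose solved angles contain gaps (NaNs from occlusion-flagged
    frames) are excluded rather than imputed.
    """
    curves = []
    for cyc in events.cycles:
        try:
            curves.append(time_normalize(series, cyc, angles))
        except GaitKinError:
            if not skip_gapped:
                raise
    return curves


# ---------------------------------------------------------------------------
# Kinematic variables and MAV
# ---------------------------------------------------------------------------

def extract_variables(curve: np.ndarray) -> KinematicVariables:
    """Initial angle (at heel strike), peaks and ROM of a 101-point curve."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (N_CYCLE_POINTS,):
        raise GaitKinError(f"curve must have {N_CYCLE_POINTS} points, got {curve.shape}")
    if not np.all(np.isfinite(curve)):
        raise GaitKinError("curve contains non-finite values")
    peak_max = float(curve.max())
    peak_min = float(curve.min())
    return KinematicVariables(initial_angle=float(curve[0]), peak_max=peak_max,
                              peak_min=peak_min, rom=peak_max - peak_min)


def mav(trial_curves) -> float:
    """Mean absolute variability of one angle across a subject's trials.

    At each of the 101 normalized points, take the across-trial maximum
    minus minimum; average those ranges over the cycle.  A single trial has
    zero variability by definition.
    """
    try:
        curves = np.atleast_2d(np.asarray(list(trial_curves), dtype=float))
    except ValueError:
        raise GaitKinError("trial curves have unequal lengths") from None
    if curves.shape[1] != N_CYCLE_POINTS:
        raise GaitKinError(f"curves must have {N_CYCLE_POINTS} points each, "
                           f"got {curves.shape[1]}")
    if not np.all(np.isfinite(curves)):
        raise GaitKinError("curves contain non-finite values")
    return float(np.mean(curves.max(axis=0) - curves.min(axis=0)))
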