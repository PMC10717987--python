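"""Global-optimization inverse kinematics.

Each frame solves

    min_q  sum_i w_i || m_i_exp - m_i_model(q) ||^2

over the 22-entry pose vector, with the experimental markers ``m_i_exp``
and the calibrated model's predicted markers ``m_i_model(q)``.  This is the
weighted least-squares marker fitting of IK-based gait analysis: because
every marker pulls on a single rigid linked chain, segment lengths stay
constant by construction and redundant markers average out soft-tissue
artifact instead of corrupting individual segment poses.

A damped (Levenberg–Marquardt) nonlinear least-squares solver with the
analytic kinematic Jacobian is used; trajectories are solved frame by frame
with warm starts from the previous frame (frame 0 starts at the calibration
pose), which also keeps angle histories continuous.  Occluded markers are
dropped from that frame's objective, and observability of the remaining
pose is verified through the rank of the residual Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import kinematic_model as km
from .calibration import CalibratedModel
from .exceptions import GaitKinError, InvalidParameterError, UnderdeterminedError
from .io import MarkerTrajectorySet


def default_min_markers(n_protocol_markers: int) -> int:
    """12 for Plugin-sized (<=16) protocols, 20 for larger ones."""
    return 12 if n_protocol_markers <= 16 else 20


@dataclass
class IKConfig:
    """Solver settings for per-frame pose estimation.

    ``weights`` maps marker names to nonnegative weights (default 1 each);
    ``tolerance`` is the cost convergence threshold (mm^2),
    ``min_markers_per_solve`` defaults per protocol size via
    :func:`default_min_markers`.  ``allow_gaps`` makes underdetermined
    frames produce NaN rows instead of raising.
    """

    weights: dict[str, float] = field(default_factory=dict)
    tolerance: float = 1e-10
    max_iterations: int = 100
    min_markers_per_solve: int | None = None
    allow_gaps: bool = False

    def weight(self, name: str) -> float:
        w = float(self.weights.get(name, 1.0))
        if w < 0:
            raise InvalidParameterError(f"negative weight for marker {name!r}")
        return w


@dataclass
class IKFrameResult:
    q: np.ndarray
    residual_rms: float
    n_markers_used: int
    converged: bool


@dataclass
class JointAngleSeries:
    """Per-frame solved pose vectors (deg / mm) with time stamps."""

    times: np.ndarray
    q: np.ndarray                      # (T, 22)
    names: tuple[str, ...] = km.Q_NAMES
    residual_rms: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.times), len(self.names)):
            raise GaitKinError(f"angle matrix shape {self.q.shape} inconsistent "
                               f"with {len(self.times)} frames x {len(self.names)} names")

    def angle(self, name: str) -> np.ndarray:
        return self.q[:, self.names.index(name)]


_RANK_RTOL = 1e-7


def _observability_check(J2d: np.ndarray) -> None:
    """Raise UnderdeterminedError naming weakly observed DOFs if rank < 22."""
    sv, vt = np.linalg.svd(J2d, compute_uv=True)[1:]
    weak = sv < _RANK_RTOL * sv[0]
    if weak.any():
        null_mix = np.abs(vt[weak]).max(axis=0)
        names = [km.Q_NAMES[i] for i in np.nonzero(null_mix > 0.3)[0]]
        raise UnderdeterminedError(
            "visible markers do not observe the full pose; weak DOFs: "
            + ", ".join(names), weak_dofs=names)


def solve_frame(cal: CalibratedModel, markers: dict[str, np.ndarray],
                q_init: np.ndarray | None = None,
                cfg: IKConfig | None = None) -> IKFrameResult:
    """Solve one frame of marker data for the 22-entry pose.

    ``markers`` maps names of *visible* markers to lab positions (mm);
    markers absent from the calibrated protocol are ignored.
    """
    cfg = cfg or IKConfig()
    q_init = cal.q0 if q_init is None else np.asarray(q_init, dtype=float)

    atts, weights = [], []
    for att in cal.attachments.markers:
        if att.name in markers and cfg.weight(att.name) > 0.0:
            atts.append(att)
            weights.append(cfg.weight(att.name))
    min_markers = (cfg.min_markers_per_solve if cfg.min_markers_per_solve is not None
                   else default_min_markers(len(cal.attachments)))
    if len(atts) < min_markers:
        raise UnderdeterminedError(
            f"only {len(atts)} usable markers (< min_markers_per_solve={min_markers})")
    if not weights or max(weights) <= 0:
        raise InvalidParameterError("at least one marker weight must be positive")

    target = np.array([markers[a.name] for a in atts])
    sqw = np.repeat(np.sqrt(weights), 3)
    plan = km.attachment_plan(cal.model, atts)

    cache: dict = {}

    def fk(x):
        key = x.tobytes()
        if key not in cache:
            cache.clear()
            P, J = km.predict_and_jacobian(cal.model, plan, len(atts), x)
            cache[key] = (P, J.reshape(len(atts) * 3, km.N_DOF))
        return cache[key]

    def fun(x):
        P, _ = fk(x)
        return sqw * (P - target).ravel()

    def jac(x):
        return sqw[:, None] * fk(x)[1]

    _observability_check(jac(q_init))
    result = least_squares(fun, q_init, jac=jac, method="lm",
                           ftol=cfg.tolerance, xtol=1e-12, gtol=1e-12,
                           max_nfev=cfg.max_iterations * (km.N_DOF + 1))
    pred, _ = fk(result.x)
    residual_rms = float(np.sqrt(np.mean(np.sum((pred - target) ** 2, axis=1))))
    return IKFrameResult(q=result.x, residual_rms=residual_rms,
                         n_markers_used=len(atts), converged=result.status > 0)


def solve_trajectory(cal: CalibratedModel, trial: MarkerTrajectorySet,
                     cfg: IKConfig | None = None) -> JointAngleSeries:
    """Solve every frame of a trial, warm-starting each from the previous.

    Underdetermined frames raise with the frame index unless
    ``cfg.allow_gaps`` is set, in which case they become NaN rows.
    """
    cfg = cfg or IKConfig()
    if trial.n_frames == 0:
        raise GaitKinError("trial contains no frames")
    Q = np.empty((trial.n_frames, km.N_DOF))
    rms = np.empty(trial.n_frames)
    q_prev = cal.q0
    for t in range(trial.n_frames):
        positions, _ = trial.frame(t)
        try:
            res = solve_frame(cal, positions, q_init=q_prev, cfg=cfg)
        except UnderdeterminedError as exc:
            if cfg.allow_gaps:
                Q[t] = np.nan
                rms[t] = np.nan
                continue
            raise UnderdeterminedError(f"frame {t}: {exc}", exc.weak_dofs) from exc
        Q[t] = res.q
        rms[t] = res.residual_rms
        q_prev = res.q
    return JointAngleSeries(times=trial.times, q=Q, residual_rms=rms)
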