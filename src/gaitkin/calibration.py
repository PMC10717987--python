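"""Subject calibration from a standing reference trial.

Scaling follows the two-step procedure used by IK-based gait pipelines:

1. *Scaling*: segment length parameters (pelvic width, thigh, shank and
   foot lengths, per side) and the static pose ``q0`` are estimated jointly
   by nonlinear least squares, minimizing the squared distances between the
   time-averaged standing marker positions and the model-predicted markers
   at their nominal (length-parameterized) attachment points.
2. *Marker offsets*: each marker's constant local offset is then re-read
   directly from the standing data — the segment-frame coordinates of its
   mean standing position at ``q0`` — so the calibrated model reproduces
   the standing trial with zero residual by construction.

The Plugin-arm model of a marker-set comparison is derived from the
Redundant calibration by dropping the 22 extra markers
(:meth:`CalibratedModel.reduce_to_plugin`), which guarantees that shared
markers carry bit-identical offsets in both arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import least_squares

from . import kinematic_model as km
from . import marker_protocol as mp
from .exceptions import ConvergenceError, GaitKinError, ProtocolError, UnderdeterminedError
from .io import MarkerTrajectorySet

LENGTH_PARAMS = ("pelvic_width", "thigh_R", "shank_R", "foot_R",
                 "thigh_L", "shank_L", "foot_L")

#: Bounds of the scaling fit: lengths within [0.5, 1.5] x nominal, static
#: joint angles within +/-45 deg of the anatomical pose, pelvis position
#: within +/-500 mm of the pelvis-marker centroid.
LENGTH_BOUND_FACTORS = (0.5, 1.5)
ANGLE_BOUND_DEG = 45.0
TRANSLATION_BOUND_MM = 500.0


@dataclass
class StandingTrial:
    """Several seconds of quiet anatomical standing."""

    frames: MarkerTrajectorySet

    def __post_init__(self):
        if self.frames.n_frames < 1:
            raise GaitKinError("standing trial must contain at least one frame")

    def mean_positions(self) -> dict[str, np.ndarray]:
        return self.frames.mean_positions()


@dataclass
class CalibratedModel:
    """A scaled model plus subject-specific marker offsets and static pose."""

    model: km.ScaledModel
    attachments: mp.MarkerProtocol
    q0: np.ndarray

    def reduce_to_plugin(self) -> "CalibratedModel":
        """The Plugin-arm model: same scaling and q0, 22 markers dropped.

        Shared markers keep bit-identical offsets, so both arms of a
        marker-set comparison differ only in which markers they use.
        """
        return CalibratedModel(self.model, mp.reduce_to_plugin(self.attachments),
                               self.q0.copy())

    # -- YAML round trip --------------------------------------------------

    def to_yaml(self) -> str:
        doc = {"lengths": {k: float(v) for k, v in self.model.lengths.items()},
               "q0": [float(v) for v in self.q0],
               "protocol": yaml.safe_load(mp.protocol_to_yaml(self.attachments))}
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CalibratedModel":
        doc = yaml.safe_load(text)
        model = km.build_model(doc["lengths"])
        proto = mp.protocol_from_yaml(yaml.safe_dump(doc["protocol"]))
        return cls(model, proto, np.asarray(doc["q0"], dtype=float))

    def save(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "CalibratedModel":
        from pathlib import Path
        return cls.from_yaml(Path(path).read_text())


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def _template_attachments(protocol: mp.MarkerProtocol, model: km.ScaledModel):
    """Protocol attachments at this model's lengths.

    Known protocols are re-resolved from their length-parameterized
    templates (this is what makes lengths observable); a custom protocol
    keeps its fixed offsets.
    """
    if protocol.name in (mp.PLUGIN, mp.REDUNDANT):
        return mp.get_protocol(protocol.name, model)
    return protocol


def estimate_scaling(standing: StandingTrial, protocol: mp.MarkerProtocol,
                     nominal: km.ScaledModel | None = None,
                     ) -> tuple[km.ScaledModel, np.ndarray]:
    """Jointly fit segment lengths and the static pose to a standing trial.

    Returns ``(scaled_model, q0)`` minimizing the summed squared distances
    between time-averaged standing markers and model-predicted markers at
    nominal attachment points.
    """
    nominal = nominal or km.build_model()
    mean = standing.mean_positions()
    used = [m for m in protocol.markers if m.name in mean]
    missing = [m.name for m in protocol.markers if m.name not in mean]
    if missing:
        raise ProtocolError(
            "markers never visible in standing trial: " + ", ".join(missing))
    target = np.array([mean[m.name] for m in used])

    pelvis_names = [m.name for m in used if m.segment == "pelvis"]
    if len(pelvis_names) < 3:
        raise UnderdeterminedError("fewer than 3 pelvis markers in standing trial")
    centroid = np.mean([mean[n] for n in pelvis_names], axis=0)

    n_len = len(LENGTH_PARAMS)
    x0 = np.concatenate([[nominal.lengths[k] for k in LENGTH_PARAMS],
                         centroid, np.zeros(km.N_DOF - 3)])
    lo = np.concatenate([[LENGTH_BOUND_FACTORS[0] * nominal.lengths[k] for k in LENGTH_PARAMS],
                         centroid - TRANSLATION_BOUND_MM,
                         np.full(km.N_DOF - 3, -ANGLE_BOUND_DEG)])
    hi = np.concatenate([[LENGTH_BOUND_FACTORS[1] * nominal.lengths[k] for k in LENGTH_PARAMS],
                         centroid + TRANSLATION_BOUND_MM,
                         np.full(km.N_DOF - 3, ANGLE_BOUND_DEG)])

    used_names = [m.name for m in used]

    def unpack(x):
        lengths = dict(zip(LENGTH_PARAMS, x[:n_len]))
        return km.build_model(lengths), x[n_len:]

    def residuals(x):
        model, q = unpack(x)
        atts = [a for a in _template_attachments(protocol, model).markers
                if a.name in mean]
        pred = km.predict_markers(model, atts, q)
        return (np.array([pred[n] for n in used_names]) - target).ravel()

    result = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                           ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=200 * len(x0))
    final_cost = float(np.sqrt(np.mean(result.fun ** 2)))
    if result.status <= 0:
        raise ConvergenceError(
            f"scaling fit did not converge (RMS residual {final_cost:.3g} mm)",
            residual=final_cost)
    sv = np.linalg.svd(result.jac, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        raise UnderdeterminedError(
            "degenerate standing marker geometry: scaling problem is rank-deficient")
    model, q0 = unpack(result.x)
    return model, np.asarray(q0)


def compute_offsets(scaled: km.ScaledModel, q0: np.ndarray,
                    standing_mean: dict[str, np.ndarray],
                    protocol: mp.MarkerProtocol) -> mp.MarkerProtocol:
    """Per-marker local offsets that reproduce the standing data exactly.

    Each offset is the segment-frame coordinate of the marker's mean
    standing position at ``q0``; predicted markers at ``q0`` therefore match
    the standing mean with zero residual.
    """
    poses = km.segment_poses(scaled, q0)
    offsets: dict[str, np.ndarray] = {}
    for m in protocol.markers:
        if m.name not in standing_mean:
            raise ProtocolError(f"marker {m.name!r} never visible in standing trial")
        R, t = poses[m.segment]
        offsets[m.name] = R.T @ (np.asarray(standing_mean[m.name]) - t)
    return mp.with_offsets(protocol, offsets)


def calibrate(standing: StandingTrial, protocol: mp.MarkerProtocol,
              nominal: km.ScaledModel | None = None) -> CalibratedModel:
    """Full standing-trial calibration: scaling, then marker offsets."""
    scaled, q0 = estimate_scaling(standing, protocol, nominal)
    attachments = compute_offsets(scaled, q0, standing.mean_positions(), protocol)
    return CalibratedModel(scaled, attachments, q0)
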