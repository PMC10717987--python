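"""Lower-extremity linked rigid-body model and forward kinematics.

The model is a 9-segment kinematic tree rooted at the pelvis: pelvis,
femur/shank/talus/foot on each side.  Joint structure gives 22 degrees of
freedom in total: a free 6-DOF pelvis-to-lab joint (3 translations + 3
rotations), 3-DOF ball joints at each hip and knee, a 1-DOF hinge at each
ankle (plantar/dorsiflexion) and a 1-DOF hinge at each subtalar joint
(eversion/inversion).

Conventions
-----------
* Lab frame: right-handed, X = walking direction, Y = subject's left,
  Z = up.  Positions are millimetres, API-level angles degrees (radians
  internally).
* Zero pose = anatomical standing with straight knees; all segment frames
  are lab-aligned at zero pose, with each frame's origin at the segment's
  proximal joint centre.
* 3-DOF joints rotate intrinsically flexion -> adduction -> internal
  rotation (Cardan sequence about the mediolateral, anteroposterior and
  longitudinal axes, per ISB practice).
* Signs: flexion, adduction, internal rotation, dorsiflexion and inversion
  are positive on both sides (left-side axes are mirrored).

The pose vector ``q`` (length 22) is ordered as in :data:`Q_NAMES`:
pelvis translation (mm, 3), pelvis orientation (deg, 3: axial rotation,
obliquity, tilt), then right hip (3), knee (3), ankle (1), subtalar (1),
then the same eight entries for the left side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError, ProtocolError

# ---------------------------------------------------------------------------
# Constants: pose-vector layout, axes, nominal dimensions
# ---------------------------------------------------------------------------

Q_NAMES: tuple[str, ...] = (
    "pelvis_tx", "pelvis_ty", "pelvis_tz",
    "pelvis_rotation", "pelvis_obliquity", "pelvis_tilt",
    "hip_flexion_R", "hip_adduction_R", "hip_rotation_R",
    "knee_flexion_R", "knee_adduction_R", "knee_rotation_R",
    "ankle_dorsiflexion_R", "subtalar_inversion_R",
    "hip_flexion_L", "hip_adduction_L", "hip_rotation_L",
    "knee_flexion_L", "knee_adduction_L", "knee_rotation_L",
    "ankle_dorsiflexion_L", "subtalar_inversion_L",
)
N_DOF = 22

ANGLE_INDICES = tuple(range(3, 22))      # entries interpreted in degrees
TRANSLATION_INDICES = (0, 1, 2)          # entries in mm

#: Fixed nominal talus height (mm); the talus is a massless intermediate
#: segment whose only role is to carry the ankle and subtalar hinge axes.
TALUS_HEIGHT = 40.0

NOMINAL_LENGTHS: dict[str, float] = {
    "pelvic_width": 240.0,
    "thigh_L": 410.0, "thigh_R": 410.0,
    "shank_L": 400.0, "shank_R": 400.0,
    "foot_L": 250.0, "foot_R": 250.0,
}

_AX_X = np.array([1.0, 0.0, 0.0])
_AX_Y = np.array([0.0, 1.0, 0.0])
_AX_Z = np.array([0.0, 0.0, 1.0])


def _side_sign(side: str) -> float:
    """+1 for left, -1 for right: the lateral direction along +Y."""
    return 1.0 if side == "L" else -1.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """One rigid segment of the kinematic tree."""

    name: str
    parent: str | None
    joint_center_offset: np.ndarray  # (3,) mm, in the parent frame
    length_parameter: str | None     # name of the scalar that sizes it
    side: str = "M"                  # L / R / M(idline)


@dataclass(frozen=True)
class JointSpec:
    """A joint: ordered rotation axes (parent anatomical frame) + DOF names."""

    name: str
    child_segment: str
    dof_axes: tuple[tuple[float, float, float], ...]
    dof_names: tuple[str, ...]


@dataclass
class ScaledModel:
    """The scaled 22-DOF lower-limb model (tree of 9 segments, 8 joints)."""

    lengths: dict[str, float]
    segments: dict[str, SegmentSpec]
    joints: dict[str, JointSpec]
    # derived, filled by build_model:
    fk_order: list[str] = field(default_factory=list, repr=False)
    joint_q_indices: dict[str, tuple[int, ...]] = field(default_factory=dict, repr=False)
    segment_dof_indices: dict[str, tuple[int, ...]] = field(default_factory=dict, repr=False)

    @property
    def n_dof(self) -> int:
        return 6 + sum(len(j.dof_axes) for j in self.joints.values())


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_model(lengths: dict[str, float] | None = None) -> ScaledModel:
    """Build the 9-segment, 22-DOF lower-extremity model.

    Parameters
    ----------
    lengths
        Mapping with keys ``pelvic_width, thigh_L/R, shank_L/R, foot_L/R``
        in mm.  Missing keys fall back to nominal adult values; all values
        must be strictly positive.
    """
    L = dict(NOMINAL_LENGTHS)
    if lengths:
        unknown = set(lengths) - set(NOMINAL_LENGTHS)
        if unknown:
            raise InvalidParameterError(f"unknown length parameters: {sorted(unknown)}")
        L.update({k: float(v) for k, v in lengths.items()})
    for k, v in L.items():
        if not np.isfinite(v) or v <= 0:
            raise InvalidParameterError(f"length parameter {k!r} must be > 0, got {v}")

    segments: dict[str, SegmentSpec] = {
        "pelvis": SegmentSpec("pelvis", None, np.zeros(3), "pelvic_width", "M"),
    }
    joints: dict[str, JointSpec] = {}
    joint_q_indices: dict[str, tuple[int, ...]] = {}
    fk_order = ["pelvis"]
    qi = 6  # first 6 entries belong to the pelvis free joint

    for side in ("R", "L"):
        s = _side_sign(side)
        ax_flex = (0.0, -1.0, 0.0)          # distal end moves anteriorly
        ax_kneeflex = (0.0, 1.0, 0.0)       # knee flexes posteriorly
        ax_add = (-s, 0.0, 0.0)             # adduction moves distal end medially
        ax_rot = (0.0, 0.0, -s)             # internal rotation turns anterior face medially

        segments[f"femur_{side}"] = SegmentSpec(
            f"femur_{side}", "pelvis",
            np.array([0.0, s * L["pelvic_width"] / 2.0, 0.0]),
            f"thigh_{side}", side)
        segments[f"shank_{side}"] = SegmentSpec(
            f"shank_{side}", f"femur_{side}",
            np.array([0.0, 0.0, -L[f"thigh_{side}"]]),
            f"shank_{side}", side)
        segments[f"talus_{side}"] = SegmentSpec(
            f"talus_{side}", f"shank_{side}",
            np.array([0.0, 0.0, -L[f"shank_{side}"]]),
            None, side)
        segments[f"foot_{side}"] = SegmentSpec(
            f"foot_{side}", f"talus_{side}",
            np.array([0.0, 0.0, -TALUS_HEIGHT]),
            f"foot_{side}", side)

        joints[f"hip_{side}"] = JointSpec(
            f"hip_{side}", f"femur_{side}",
            (ax_flex, ax_add, ax_rot),
            (f"hip_flexion_{side}", f"hip_adduction_{side}", f"hip_rotation_{side}"))
        joints[f"knee_{side}"] = JointSpec(
            f"knee_{side}", f"shank_{side}",
            (ax_kneeflex, ax_add, ax_rot),
            (f"knee_flexion_{side}", f"knee_adduction_{side}", f"knee_rotation_{side}"))
        joints[f"ankle_{side}"] = JointSpec(
            f"ankle_{side}", f"talus_{side}", (ax_flex,),
            (f"ankle_dorsiflexion_{side}",))
        joints[f"subtalar_{side}"] = JointSpec(
            f"subtalar_{side}", f"foot_{side}", (ax_add,),
            (f"subtalar_inversion_{side}",))

        for jname in (f"hip_{side}", f"knee_{side}", f"ankle_{side}", f"subtalar_{side}"):
            n = len(joints[jname].dof_axes)
            joint_q_indices[jname] = tuple(range(qi, qi + n))
            qi += n
        fk_order += [f"femur_{side}", f"shank_{side}", f"talus_{side}", f"foot_{side}"]

    assert qi == N_DOF
    # sanity against the documented layout
    for jname, idx in joint_q_indices.items():
        assert tuple(Q_NAMES[i] for i in idx) == joints[jname].dof_names

    # every DOF whose motion moves a given segment (pelvis DOFs move all)
    child_joint = {j.child_segment: j.name for j in joints.values()}
    seg_dofs: dict[str, tuple[int, ...]] = {"pelvis": tuple(range(6))}
    for name in fk_order[1:]:
        parent = segments[name].parent
        seg_dofs[name] = seg_dofs[parent] + joint_q_indices[child_joint[name]]

    return ScaledModel(lengths=L, segments=segments, joints=joints,
                       fk_order=fk_order, joint_q_indices=joint_q_indices,
                       segment_dof_indices=seg_dofs)


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

def _rot(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


#: Pelvis orientation sequence: axial rotation (about Z), obliquity (about X),
#: tilt (about -Y, so positive tilt pitches the pelvis anteriorly).
_PELVIS_AXES = (_AX_Z, _AX_X, -_AX_Y)


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def _check_q(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (N_DOF,):
        raise InvalidParameterError(f"pose vector must have length {N_DOF}, got shape {q.shape}")
    return q


def segment_poses(model: ScaledModel, q) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pose (rotation matrix R, origin t in mm, lab frame) of every segment.

    ``q`` is the 22-entry pose vector in API units (mm / degrees).
    """
    poses, _, _ = _fk(model, _check_q(q), want_jacobian_info=False)
    return poses


def _fk(model: ScaledModel, q: np.ndarray, want_jacobian_info: bool = True):
    """Forward kinematics; optionally collects per-DOF world axes/centres.

    Returns ``(poses, dof_axis_world, dof_center_world)`` where for a
    rotational DOF *i*, ``d p/d theta_i = axis_i x (p - center_i)`` (radians)
    for any point p on a segment distal to that DOF.
    """
    ang = np.deg2rad(q)
    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    axes = np.zeros((N_DOF, 3)) if want_jacobian_info else None
    centers = np.zeros((N_DOF, 3)) if want_jacobian_info else None

    t_pelvis = q[:3].copy()
    R = np.eye(3)
    for k, axis in enumerate(_PELVIS_AXES):
        if want_jacobian_info:
            axes[3 + k] = R @ axis
            centers[3 + k] = t_pelvis
        R = R @ _rot(axis, ang[3 + k])
    if want_jacobian_info:
        axes[0], axes[1], axes[2] = _AX_X, _AX_Y, _AX_Z
    poses["pelvis"] = (R, t_pelvis)

    child_joint = {j.child_segment: j for j in model.joints.values()}
    for name in model.fk_order[1:]:
        seg = model.segments[name]
        joint = child_joint[name]
        Rp, tp = poses[seg.parent]
        t = tp + Rp @ seg.joint_center_offset
        R = Rp
        for axis, qi in zip(joint.dof_axes, model.joint_q_indices[joint.name]):
            a = np.asarray(axis)
            if want_jacobian_info:
                axes[qi] = R @ a
                centers[qi] = t
            R = R @ _rot(a, ang[qi])
        poses[name] = (R, t)

    return poses, axes, centers


def predict_markers(model: ScaledModel, attachments, q) -> dict[str, np.ndarray]:
    """Predicted lab-frame marker positions (mm) for a pose vector.

    ``attachments`` is an iterable of objects with ``name``, ``segment`` and
    ``local_offset`` attributes (e.g. :class:`~gaitkin.marker_protocol.MarkerAttachment`).
    """
    q = _check_q(q)
    poses = segment_poses(model, q)
    out: dict[str, np.ndarray] = {}
    for att in attachments:
        if att.segment not in poses:
            raise ProtocolError(f"marker {att.name!r} attached to unknown segment {att.segment!r}")
        R, t = poses[att.segment]
        out[att.name] = t + R @ np.asarray(att.local_offset, dtype=float)
    return out


def predict_markers_array(model: ScaledModel, attachments, q) -> np.ndarray:
    """Like :func:`predict_markers` but returns an (n_markers, 3) array."""
    pred = predict_markers(model, attachments, q)
    return np.array(list(pred.values()))


def attachment_plan(model: ScaledModel, attachments) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Group attachments by segment for vectorized prediction.

    Returns ``[(segment, marker_indices, offsets (k, 3)), ...]``; marker
    indices refer to the order of ``attachments``.
    """
    by_seg: dict[str, list[int]] = {}
    atts = list(attachments)
    for m, att in enumerate(atts):
        if att.segment not in model.segments:
            raise ProtocolError(f"marker {att.name!r} attached to unknown segment {att.segment!r}")
        by_seg.setdefault(att.segment, []).append(m)
    plan = []
    for seg, idx in by_seg.items():
        rot_dofs = np.array([i for i in model.segment_dof_indices[seg]
                             if i not in TRANSLATION_INDICES], dtype=int)
        plan.append((seg, np.array(idx),
                     np.array([atts[m].local_offset for m in idx], dtype=float),
                     rot_dofs))
    return plan


def predict_and_jacobian(model: ScaledModel, plan, n_markers: int, q,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Marker positions and analytic Jacobian for a precomputed plan.

    ``J`` has shape (M, 3, 22); angular columns are mm/degree, pelvis
    translation columns mm/mm, matching the API units of ``q``.
    """
    q = _check_q(q)
    poses, axes, centers = _fk(model, q, want_jacobian_info=True)
    P = np.empty((n_markers, 3))
    J = np.zeros((n_markers, 3, N_DOF))
    deg = np.pi / 180.0
    eye3 = np.eye(3)
    for seg, idx, offs, rot_dofs in plan:
        R, t = poses[seg]
        Pm = t + offs @ R.T
        P[idx] = Pm
        J[idx, :, 0:3] = eye3
        A = axes[rot_dofs]                          # (d, 3) world joint axes
        D = Pm[:, None, :] - centers[rot_dofs]      # (k, d, 3) lever arms
        cross = np.empty_like(D)                    # A x D, expanded
        cross[..., 0] = A[:, 1] * D[..., 2] - A[:, 2] * D[..., 1]
        cross[..., 1] = A[:, 2] * D[..., 0] - A[:, 0] * D[..., 2]
        cross[..., 2] = A[:, 0] * D[..., 1] - A[:, 1] * D[..., 0]
        J[np.ix_(idx, (0, 1, 2), rot_dofs)] = np.swapaxes(cross, 1, 2) * deg
    return P, J


def marker_jacobian(model: ScaledModel, attachments, q) -> tuple[np.ndarray, np.ndarray]:
    """Analytic kinematic Jacobian of marker positions w.r.t. the pose vector.

    Returns ``(positions, J)`` with ``positions`` of shape (M, 3) and ``J``
    of shape (M, 3, 22) in the same API units as ``q`` (mm / degrees).
    Marker rows follow the order of ``attachments``.
    """
    atts = list(attachments)
    plan = attachment_plan(model, atts)
    return predict_and_jacobian(model, plan, len(atts), q)


def zero_pose() -> np.ndarray:
    """The 22-entry zero (anatomical standing, pelvis at lab origin) pose."""
    return np.zeros(N_DOF)
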