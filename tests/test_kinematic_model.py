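"""Forward kinematics of the 22-DOF lower-limb model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitkin import kinematic_model as km
from gaitkin.exceptions import InvalidParameterError, ProtocolError


def _random_q(rng, angle_range=30.0):
    q = rng.uniform(-angle_range, angle_range, km.N_DOF)
    q[:3] = rng.uniform(-200.0, 200.0, 3)
    return q


class TestBuildModel:
    def test_structure(self, nominal_model):
        m = nominal_model
        assert m.n_dof == 22
        assert len(m.segments) == 9
        assert len(m.joints) == 8
        for side in "LR":
            assert len(m.joints[f"hip_{side}"].dof_axes) == 3
            assert len(m.joints[f"knee_{side}"].dof_axes) == 3
            assert len(m.joints[f"ankle_{side}"].dof_axes) == 1
            assert len(m.joints[f"subtalar_{side}"].dof_axes) == 1

    def test_tree_rooted_at_pelvis(self, nominal_model):
        segs = nominal_model.segments
        assert segs["pelvis"].parent is None
        for name, seg in segs.items():
            if name != "pelvis":
                assert seg.parent in segs

    @pytest.mark.parametrize("bad", [{"thigh_L": 0.0}, {"shank_R": -5.0},
                                     {"pelvic_width": np.nan}])
    def test_nonpositive_length_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            km.build_model(bad)

    def test_unknown_length_rejected(self):
        with pytest.raises(InvalidParameterError, match="unknown"):
            km.build_model({"femur_len": 400.0})

    def test_asymmetric_lengths_allowed(self):
        m = km.build_model({"thigh_L": 390.0, "thigh_R": 430.0})
        assert m.lengths["thigh_L"] != m.lengths["thigh_R"]


class TestSegmentPoses:
    def test_zero_pose_is_reference(self, nominal_model):
        poses = km.segment_poses(nominal_model, km.zero_pose())
        for R, _ in poses.values():
            np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        _, t_knee = poses["shank_R"]
        np.testing.assert_allclose(
            t_knee, [0.0, -nominal_model.lengths["pelvic_width"] / 2,
                     -nominal_model.lengths["thigh_R"]])

    def test_pelvis_translation_is_rigid_shift(self, nominal_model):
        q = km.zero_pose()
        q[:3] = [10.0, 0.0, 0.0]
        ref = km.segment_poses(nominal_model, km.zero_pose())
        shifted = km.segment_poses(nominal_model, q)
        for name in ref:
            np.testing.assert_allclose(shifted[name][1] - ref[name][1],
                                       [10.0, 0.0, 0.0], atol=1e-12)

    def test_right_hip_flexion_90_matches_hand_composition(self, nominal_model):
        # independent oracle: compose the two-link chain by hand
        q = km.zero_pose()
        q[km.Q_NAMES.index("hip_flexion_R")] = 90.0
        poses = km.segment_poses(nominal_model, q)
        R_femur, t_femur = poses["femur_R"]
        c, s = np.cos(np.pi / 2), np.sin(np.pi / 2)
        # rotation about (0,-1,0) by 90 deg
        R_expected = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
        np.testing.assert_allclose(R_femur, R_expected, atol=1e-12)
        np.testing.assert_allclose(
            t_femur, [0.0, -nominal_model.lengths["pelvic_width"] / 2, 0.0])
        # knee center swings anteriorly: down-vector maps to +X
        _, t_shank = poses["shank_R"]
        np.testing.assert_allclose(
            t_shank, [nominal_model.lengths["thigh_R"],
                      -nominal_model.lengths["pelvic_width"] / 2, 0.0], atol=1e-9)

    def test_wrong_length_pose_rejected(self, nominal_model):
        with pytest.raises(InvalidParameterError):
            km.segment_poses(nominal_model, np.zeros(21))


class TestPredictMarkers:
    def test_zero_pose_positions_are_offsets_from_reference(self, nominal_model, redundant):
        poses = km.segment_poses(nominal_model, km.zero_pose())
        pred = km.predict_markers(nominal_model, redundant.markers, km.zero_pose())
        for att in redundant.markers:
            _, t = poses[att.segment]
            np.testing.assert_allclose(pred[att.name], t + att.local_offset)

    def test_subset_consistency(self, nominal_model, plugin, redundant, rng):
        q = _random_q(rng)
        full = km.predict_markers(nominal_model, redundant.markers, q)
        sub = km.predict_markers(nominal_model, plugin.markers, q)
        for name, pos in sub.items():
            np.testing.assert_array_equal(pos, full[name])

    def test_unknown_segment_rejected(self, nominal_model):
        from gaitkin.marker_protocol import MarkerAttachment
        bad = MarkerAttachment("X", "tibia_R", [0, 0, 0], "R")
        with pytest.raises(ProtocolError, match="tibia_R"):
            km.predict_markers(nominal_model, [bad], km.zero_pose())

    def test_brute_force_transform_chain(self, nominal_model, rng):
        """Marker positions agree with an independent walk up the tree."""
        from gaitkin.marker_protocol import MarkerAttachment
        q = _random_q(rng)
        ang = np.deg2rad(q)
        atts = [MarkerAttachment("P1", "foot_R", rng.uniform(-50, 50, 3), "R"),
                MarkerAttachment("P2", "shank_L", rng.uniform(-50, 50, 3), "L")]
        pred = km.predict_markers(nominal_model, atts, q)

        from scipy.spatial.transform import Rotation

        def rot(axis, angle_rad):
            return Rotation.from_rotvec(np.asarray(axis) * angle_rad).as_matrix()

        def oracle(att):
            # accumulate transforms from segment up to the lab frame
            chain = []
            seg = nominal_model.segments[att.segment]
            joints_by_child = {j.child_segment: j for j in nominal_model.joints.values()}
            while seg.parent is not None:
                chain.append(seg)
                seg = nominal_model.segments[seg.parent]
            p = np.asarray(att.local_offset, dtype=float)
            for seg in chain:
                joint = joints_by_child[seg.name]
                R = np.eye(3)
                for axis, qi in zip(joint.dof_axes,
                                    nominal_model.joint_q_indices[joint.name]):
                    R = R @ rot(axis, ang[qi])
                p = seg.joint_center_offset + R @ p
            Rp = np.eye(3)
            for k, axis in enumerate(((0, 0, 1), (1, 0, 0), (0, -1, 0))):
                Rp = Rp @ rot(axis, ang[3 + k])
            return q[:3] + Rp @ p

        for att in atts:
            np.testing.assert_allclose(pred[att.name], oracle(att), atol=1e-9)

    def test_analytic_jacobian_matches_finite_differences(self, nominal_model, redundant, rng):
        q = _random_q(rng)
        P, J = km.marker_jacobian(nominal_model, redundant.markers, q)
        eps = 1e-6
        for i in range(km.N_DOF):
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            fd = (km.predict_markers_array(nominal_model, redundant.markers, qp)
                  - km.predict_markers_array(nominal_model, redundant.markers, qm)) / (2 * eps)
            np.testing.assert_allclose(J[:, :, i], fd, atol=1e-5)


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_rigid_body_distances_pose_invariant(self, seed):
        """Same-segment inter-marker distances never depend on the pose."""
        model = km.build_model()
        from gaitkin.marker_protocol import redundant_marker_set
        proto = redundant_marker_set(model)
        rng = np.random.default_rng(seed)
        q1, q2 = _random_q(rng, 60.0), _random_q(rng, 60.0)
        p1 = km.predict_markers(model, proto.markers, q1)
        p2 = km.predict_markers(model, proto.markers, q2)
        by_seg = {}
        for att in proto.markers:
            by_seg.setdefault(att.segment, []).append(att.name)
        for names in by_seg.values():
            for a in names:
                for b in names:
                    d1 = np.linalg.norm(p1[a] - p1[b])
                    d2 = np.linalg.norm(p2[a] - p2[b])
                    assert d1 == pytest.approx(d2, abs=1e-8)

    def test_left_right_mirror_symmetry(self, nominal_model, redundant, rng):
        """Swapping left/right joint angles mirrors marker positions in Y."""
        q = km.zero_pose()
        vals = rng.uniform(-30, 30, 8)
        for k, base in enumerate(["hip_flexion", "hip_adduction", "hip_rotation",
                                  "knee_flexion", "knee_adduction", "knee_rotation",
                                  "ankle_dorsiflexion", "subtalar_inversion"]):
            q[km.Q_NAMES.index(f"{base}_R")] = vals[k]
        q_mirror = km.zero_pose()
        for k, base in enumerate(["hip_flexion", "hip_adduction", "hip_rotation",
                                  "knee_flexion", "knee_adduction", "knee_rotation",
                                  "ankle_dorsiflexion", "subtalar_inversion"]):
            q_mirror[km.Q_NAMES.index(f"{base}_L")] = vals[k]
        p = km.predict_markers(nominal_model, redundant.markers, q)
        pm = km.predict_markers(nominal_model, redundant.markers, q_mirror)
        flip = np.array([1.0, -1.0, 1.0])
        for name, pos in p.items():
            partner = ("L" if name[0] == "R" else "R") + name[1:]
            np.testing.assert_allclose(pm[partner], pos * flip, atol=1e-9)
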