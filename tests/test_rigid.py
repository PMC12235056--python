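"""Pose estimation, CT registration, landmark replay and mirroring."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from girdlekin.rigid import (
    BoneAnatomy,
    ClusterModel,
    PoseEstimationError,
    RegistrationError,
    RigidTransform,
    estimate_pose,
    estimate_pose_series,
    landmark_trajectory,
    mirror_anatomy,
    mirror_points,
    register_ct,
)
from conftest import random_rotation

PLATE = np.array([[0.0, 0, 0], [80, 0, 0], [64, 56, 12], [12, 60, -10]])


def make_model(name="seg"):
    return ClusterModel(segment=name, positions={f"m{i}": p for i, p in enumerate(PLATE)})


def brute_force_pose(model: np.ndarray, observed: np.ndarray):
    """Independent nonlinear minimiser over rotation-vector space.

    Translation is profiled out analytically (optimal t aligns centroids for
    any R), leaving a 3-parameter rotation search started from several
    points covering SO(3).
    """
    mc, oc = model.mean(axis=0), observed.mean(axis=0)
    A, B = model - mc, observed - oc

    def cost(w):
        R = Rotation.from_rotvec(w).as_matrix()
        return np.sum((A @ R.T - B) ** 2)

    starts = [np.zeros(3)] + [np.pi / 2 * e for e in np.eye(3)] + [-np.pi / 2 * e for e in np.eye(3)] + [
        np.array([np.pi, 0, 0]), np.array([0, np.pi, 0]), np.array([0, 0, np.pi])
    ]
    best = min((minimize(cost, w0, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000}) for w0 in starts), key=lambda r: r.fun)
    R = Rotation.from_rotvec(best.x).as_matrix()
    return R, oc - R @ mc


def rotation_angle(Ra, Rb):
    """Geodesic distance between two rotations, radians (stable near zero)."""
    return float(Rotation.from_matrix(Ra.T @ Rb).magnitude())


class TestEstimatePose:
    def test_identity_on_model(self):
        model = make_model()
        tf, rms = estimate_pose(model, dict(model.positions))
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tf.translation, 0, atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_of_known_transform(self, rng):
        model = make_model()
        for _ in range(20):
            R = random_rotation(rng)
            t = rng.normal(scale=100, size=3)
            obs = {k: R @ v + t for k, v in model.positions.items()}
            tf, rms = estimate_pose(model, obs)
            assert rotation_angle(tf.rotation, R) < 1e-10
            assert np.allclose(tf.translation, t, atol=1e-8)
            assert rms < 1e-10

    def test_matches_brute_force_on_noisy_observations(self, rng):
        """SVD Procrustes equals an independent nonlinear minimiser."""
        model = make_model()
        m = model.as_array()
        for _ in range(25):
            R = random_rotation(rng)
            t = rng.normal(scale=50, size=3)
            obs = m @ R.T + t + rng.normal(scale=0.3, size=m.shape)
            tf, _ = estimate_pose(model, dict(zip(model.labels, obs)))
            R_bf, t_bf = brute_force_pose(m, obs)
            assert rotation_angle(tf.rotation, R_bf) < 1e-6

    def test_equivariance_under_pre_rotation(self, rng):
        model = make_model()
        m = model.as_array()
        obs = m + rng.normal(scale=0.2, size=m.shape)
        tf, _ = estimate_pose(model, dict(zip(model.labels, obs)))
        Q = random_rotation(rng)
        tf_q, _ = estimate_pose(model, dict(zip(model.labels, obs @ Q.T)))
        assert rotation_angle(tf_q.rotation, Q @ tf.rotation) < 1e-9
        assert np.allclose(tf_q.translation, Q @ tf.translation, atol=1e-8)

    def test_three_visible_markers_suffice_two_fail(self):
        model = make_model()
        obs = dict(model.positions)
        obs.pop("m3")
        tf, _ = estimate_pose(model, obs)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-10)
        obs.pop("m2")
        with pytest.raises(PoseEstimationError, match="visible"):
            estimate_pose(model, obs)

    def test_series_matches_per_frame(self, rng):
        model = make_model()
        m = model.as_array()
        n = 15
        pos = np.stack([m + rng.normal(scale=0.2, size=m.shape) for _ in range(n)])
        mask = np.ones((n, 4), dtype=bool)
        mask[5, 3] = False  # one frame with an occluded marker
        R, t, rms = estimate_pose_series(model, pos, mask, model.labels)
        for f in range(n):
            obs = {model.labels[j]: pos[f, j] for j in range(4) if mask[f, j]}
            tf, r = estimate_pose(model, obs)
            assert rotation_angle(R[f], tf.rotation) < 1e-10
            assert rms[f] == pytest.approx(r, abs=1e-10)


class TestRigidTransform:
    def test_compose_inverse_roundtrip(self, rng):
        R1, R2 = random_rotation(rng), random_rotation(rng)
        a = RigidTransform(R1, rng.normal(size=3))
        b = RigidTransform(R2, rng.normal(size=3))
        p = rng.normal(size=(7, 3))
        assert np.allclose(a.compose(b).apply(p), a.apply(b.apply(p)), atol=1e-10)
        assert np.allclose(a.inverse().apply(a.apply(p)), p, atol=1e-10)

    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestRegistration:
    def anatomy(self, markers):
        return BoneAnatomy(
            bone="clavicle",
            landmarks={"SC": (0, 0, 0), "AC": (10, 30, 160)},
            markers=markers,
        )

    def test_identity_when_frames_coincide(self):
        model = make_model("clavicle")
        reg, rms = register_ct(self.anatomy(dict(model.positions)), model)
        assert np.allclose(reg.rotation, np.eye(3), atol=1e-12)
        assert rms < 1e-12

    def test_known_offset_recovered_and_landmarks_constant(self, rng):
        model = make_model("clavicle")
        R = random_rotation(rng)
        t = rng.normal(scale=80, size=3)
        # CT frame differs from the technical frame by (R, t)^-1
        ct_markers = {k: R.T @ (v - t) for k, v in model.positions.items()}
        reg, rms = register_ct(self.anatomy(ct_markers), model)
        assert rotation_angle(reg.rotation, R) < 1e-10
        assert np.allclose(reg.translation, t, atol=1e-8)
        assert rms < 1e-9

    def test_residual_threshold_names_bone(self):
        model = make_model("clavicle")
        bad = {k: v + np.array([3.0, -2.0, 5.0]) * (i % 2) for i, (k, v) in enumerate(model.positions.items())}
        with pytest.raises(RegistrationError, match="clavicle"):
            register_ct(self.anatomy(bad), model, max_residual_mm=0.5)

    def test_landmark_trajectory_static_and_rigid(self, rng):
        reg = RigidTransform(random_rotation(rng), rng.normal(size=3))
        n = 30
        Rs = np.stack([random_rotation(rng) for _ in range(n)])
        ts = rng.normal(scale=20, size=(n, 3))
        p1, p2 = np.array([10.0, 5.0, -3.0]), np.array([-25.0, 40.0, 8.0])
        tr1 = landmark_trajectory(p1, reg, Rs, ts)
        tr2 = landmark_trajectory(p2, reg, Rs, ts)
        d = np.linalg.norm(tr1 - tr2, axis=1)
        assert np.allclose(d, d[0], atol=1e-9)  # rigid distance preservation
        static = landmark_trajectory(p1, reg, np.repeat(np.eye(3)[None], 5, 0), np.zeros((5, 3)))
        assert np.allclose(static, static[0], atol=1e-12)


class TestMirroring:
    def test_involution(self, rng):
        pts = rng.normal(size=(10, 3))
        assert np.allclose(mirror_points(mirror_points(pts)), pts, atol=1e-15)

    def test_point_map_is_reflection(self):
        from girdlekin.rigid import MIRROR_MATRIX

        assert np.linalg.det(MIRROR_MATRIX) == pytest.approx(-1.0)
        assert np.allclose(MIRROR_MATRIX @ MIRROR_MATRIX, np.eye(3))

    def test_anatomy_mirror_preserves_labels_and_distances(self, skeleton):
        anat = skeleton.anatomies["scapula"]
        mirrored = mirror_anatomy(anat)
        assert set(mirrored.landmarks) == set(anat.landmarks)
        a = anat.landmarks["AA"] - anat.landmarks["TS"]
        b = mirrored.landmarks["AA"] - mirrored.landmarks["TS"]
        assert np.linalg.norm(a) == pytest.approx(np.linalg.norm(b))
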