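"""Rigid-body pose estimation and CT-to-tracking fusion.

Each bony segment (thorax, clavicle, scapula, humerus) carries a cluster of
four reflective markers on intracortical pins.  The per-frame pose of the
cluster's technical frame is estimated by orthogonal Procrustes (SVD with a
reflection guard).  Anatomy digitised in the CT frame -- ISB landmarks and
the dorsal acromial reference point -- is fused into the tracking stream by
registering the CT-segmented marker positions onto the cluster model, after
which any CT-frame point can be replayed through the pose series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "RigidTransform",
    "ClusterModel",
    "BoneAnatomy",
    "PoseEstimationError",
    "RegistrationError",
    "estimate_pose",
    "estimate_pose_series",
    "register_ct",
    "landmark_trajectory",
    "mirror_points",
    "mirror_anatomy",
]

_ORTHO_TOL = 1e-9

THORAX_LANDMARKS = ("IJ", "C7", "PX", "T8")
CLAVICLE_LANDMARKS = ("SC", "AC")
SCAPULA_LANDMARKS = ("AA", "TS", "AI")
HUMERUS_LANDMARKS = ("GH", "EL", "EM")

REQUIRED_LANDMARKS: dict[str, tuple[str, ...]] = {
    "thorax": THORAX_LANDMARKS,
    "clavicle": CLAVICLE_LANDMARKS,
    "scapula": SCAPULA_LANDMARKS,
    "humerus": HUMERUS_LANDMARKS,
}


class PoseEstimationError(ValueError):
    """Raised when a cluster pose cannot be estimated for a frame."""


class RegistrationError(ValueError):
    """Raised when CT-to-technical-frame registration fails or is too poor."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t`` (rotation in SO(3), mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.isfinite(R).all() or not np.isfinite(t).all():
            raise ValueError("non-finite rigid transform")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant is not +1 (improper transform)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class ClusterModel:
    """Marker cluster geometry in its technical frame (mm).

    ``positions`` maps marker label -> 3-vector.  At least three
    non-collinear markers are required so the pose is well conditioned.
    """

    segment: str
    positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        pos = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.positions.items()}
        if len(pos) < 3:
            raise ValueError(f"cluster '{self.segment}' needs >=3 markers, got {len(pos)}")
        arr = np.array(list(pos.values()))
        if not np.isfinite(arr).all():
            raise ValueError(f"cluster '{self.segment}' has non-finite marker positions")
        if _collinear(arr):
            raise ValueError(f"cluster '{self.segment}' markers are collinear")
        object.__setattr__(self, "positions", pos)

    @property
    def labels(self) -> list[str]:
        return list(self.positions)

    def as_array(self, labels: list[str] | None = None) -> np.ndarray:
        labels = labels if labels is not None else self.labels
        return np.array([self.positions[l] for l in labels])


@dataclass(frozen=True)
class BoneAnatomy:
    """Per-bone CT-frame anatomy: ISB landmarks plus segmented marker positions.

    The scapula additionally carries ``P_dorsal``, the most dorsal point on
    the acromion at the AC joint, whose displacement is the translational
    outcome of the analysis.
    """

    bone: str
    landmarks: Mapping[str, np.ndarray]
    markers: Mapping[str, np.ndarray]
    p_dorsal: np.ndarray | None = None

    def __post_init__(self) -> None:
        lm = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.landmarks.items()}
        mk = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.markers.items()}
        required = REQUIRED_LANDMARKS.get(self.bone, ())
        missing = [name for name in required if name not in lm]
        if missing:
            raise ValueError(f"bone '{self.bone}' missing landmarks: {missing}")
        if self.bone == "scapula":
            if self.p_dorsal is None:
                raise ValueError("scapula anatomy requires the acromial point P_dorsal")
            object.__setattr__(self, "p_dorsal", np.asarray(self.p_dorsal, dtype=float).reshape(3))
        object.__setattr__(self, "landmarks", lm)
        object.__setattr__(self, "markers", mk)


def _collinear(points: np.ndarray, rtol: float = 1e-8) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= rtol * max(s[0], 1.0)


def _procrustes(model: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation+translation mapping model points onto observed.

    Kabsch/SVD solution of min Σ‖R m_i + t − o_i‖²; the reflection guard
    flips the smallest singular direction when the raw optimum is improper.
    """
    mc = model.mean(axis=0)
    oc = observed.mean(axis=0)
    H = (model - mc).T @ (observed - oc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = oc - R @ mc
    return R, t


def estimate_pose(
    model: ClusterModel, observed: Mapping[str, np.ndarray]
) -> tuple[RigidTransform, float]:
    """Estimate the technical-frame-to-lab pose from one frame of markers.

    ``observed`` maps marker label -> lab position; markers absent from it
    (occluded) are dropped.  Returns the transform and the residual RMS (mm).
    """
    labels = [l for l in model.labels if l in observed]
    if len(labels) < 3:
        raise PoseEstimationError(
            f"segment '{model.segment}': only {len(labels)} visible markers (need >=3)"
        )
    m = model.as_array(labels)
    o = np.array([np.asarray(observed[l], dtype=float).reshape(3) for l in labels])
    if not np.isfinite(o).all():
        raise PoseEstimationError(f"segment '{model.segment}': non-finite observation")
    if _collinear(m):
        raise PoseEstimationError(f"segment '{model.segment}': visible subset is collinear")
    R, t = _procrustes(m, o)
    resid = o - (m @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(R, t), rms


def estimate_pose_series(
    model: ClusterModel,
    positions: np.ndarray,
    mask: np.ndarray,
    labels: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pose estimation over a whole trial.

    Parameters
    ----------
    positions : (n_frames, n_markers, 3) lab positions (mm).
    mask : (n_frames, n_markers) visibility.
    labels : marker labels matching the positions axis; markers not in the
        cluster model are ignored.

    Returns
    -------
    rotations : (n_frames, 3, 3), translations : (n_frames, 3),
    residual_rms : (n_frames,)
    """
    idx = [i for i, l in enumerate(labels) if l in model.positions]
    if len(idx) < 3:
        raise PoseEstimationError(
            f"segment '{model.segment}': trajectory holds {len(idx)} cluster markers"
        )
    lab = [labels[i] for i in idx]
    m_full = model.as_array(lab)
    obs = positions[:, idx, :]
    vis = mask[:, idx]
    n = obs.shape[0]

    rotations = np.empty((n, 3, 3))
    translations = np.empty((n, 3))
    rms = np.empty(n)

    full = vis.all(axis=1)
    if full.any():
        R, t, r = _procrustes_batch(m_full, obs[full])
        rotations[full], translations[full], rms[full] = R, t, r
    for f in np.nonzero(~full)[0]:
        frame_obs = {lab[j]: obs[f, j] for j in range(len(lab)) if vis[f, j]}
        tf, r = estimate_pose(model, frame_obs)
        rotations[f], translations[f], rms[f] = tf.rotation, tf.translation, r
    return rotations, translations, rms


def _procrustes_batch(model: np.ndarray, observed: np.ndarray):
    """Batched Procrustes: model (m,3) onto observed (n,m,3)."""
    mc = model.mean(axis=0)
    oc = observed.mean(axis=1)
    A = model - mc
    B = observed - oc[:, None, :]
    H = np.einsum("mi,nmj->nij", A, B)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nji,nkj->nik", Vt, U))  # det(V @ U^T)
    D = np.repeat(np.eye(3)[None], len(observed), axis=0)
    D[:, 2, 2] = np.sign(det)
    # R_n = V_n @ D_n @ U_n^T with the smallest singular direction flipped
    R = np.einsum("nji,njk,nlk->nil", Vt, D, U)
    t = oc - np.einsum("nij,j->ni", R, mc)
    pred = np.einsum("nij,mj->nmi", R, model) + t[:, None, :]
    rms = np.sqrt(np.mean(np.sum((observed - pred) ** 2, axis=2), axis=1))
    return R, t, rms


def register_ct(
    anatomy: BoneAnatomy, model: ClusterModel, max_residual_mm: float = 1.0
) -> tuple[RigidTransform, float]:
    """Register the CT frame onto the cluster technical frame.

    The same physical markers are segmented in CT and present in the cluster
    model; a Procrustes fit of CT marker positions onto the technical-frame
    positions gives the CT->technical transform, after which CT-digitised
    landmarks are constant in the technical frame.
    """
    labels = [l for l in model.labels if l in anatomy.markers]
    if len(labels) < 3:
        raise RegistrationError(
            f"bone '{anatomy.bone}': {len(labels)} corresponding markers between CT and cluster"
        )
    ct = np.array([anatomy.markers[l] for l in labels])
    tech = model.as_array(labels)
    R, t = _procrustes(ct, tech)
    resid = tech - (ct @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    if rms > max_residual_mm:
        raise RegistrationError(
            f"bone '{anatomy.bone}': registration residual {rms:.3f} mm exceeds "
            f"{max_residual_mm} mm"
        )
    return RigidTransform(R, t), rms


def landmark_trajectory(
    point_ct: np.ndarray,
    registration: RigidTransform,
    rotations: np.ndarray,
    translations: np.ndarray,
) -> np.ndarray:
    """Replay a CT-frame point through a pose series into the lab frame.

    ``position(t) = Pose(t) ∘ Registration`` applied to the point; returns
    an (n_frames, 3) trajectory in mm.
    """
    rotations = np.asarray(rotations)
    translations = np.asarray(translations)
    if rotations.shape[0] != translations.shape[0]:
        raise ValueError("pose series rotation/translation length mismatch")
    p_tech = registration.apply(np.asarray(point_ct, dtype=float).reshape(3))
    return np.einsum("nij,j->ni", rotations, p_tech) + translations


# --- side mirroring -------------------------------------------------------

#: Sagittal-plane reflection in the lab frame (X anterior, Y superior, Z right):
#: the lateral axis is negated.  Applied to *both* the marker data and the CT
#: anatomy of a left shoulder, it produces a geometrically valid right
#: shoulder, so all downstream ISB sign conventions apply unchanged.
MIRROR_MATRIX = np.diag([1.0, 1.0, -1.0])


def mirror_points(points: np.ndarray) -> np.ndarray:
    """Reflect (..., 3) points across the lab sagittal plane (det = -1 map)."""
    return np.asarray(points, dtype=float) @ MIRROR_MATRIX.T


def mirror_anatomy(anatomy: BoneAnatomy) -> BoneAnatomy:
    """Mirror a bone's CT-frame anatomy across the sagittal plane."""
    return BoneAnatomy(
        bone=anatomy.bone,
        landmarks={k: mirror_points(v) for k, v in anatomy.landmarks.items()},
        markers={k: mirror_points(v) for k, v in anatomy.markers.items()},
        p_dorsal=None if anatomy.p_dorsal is None else mirror_points(anatomy.p_dorsal),
    )
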