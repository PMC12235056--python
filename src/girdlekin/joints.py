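"""Acromioclavicular and thoracohumeral joint kinematics.

AC rotations are the Euler angles of the scapula anatomical frame relative
to the clavicle anatomical frame in the mobile Y-X-Z sequence
(retraction(-)/protraction(+), lateral(-)/medial(+) rotation,
anterior(-)/posterior(+) tilt).  AC displacements are the components of the
most dorsal acromial point expressed along the clavicle (joint) frame axes
(superior+, anterior+, lateral+).  Humerus-relative-to-thorax orientation is
decomposed in the Y-X-Y sequence as plane of elevation, elevation and axial
rotation.

Both sequences have a removable degeneracy (gimbal lock): Y-X-Z at
|second angle| = 90 deg, Y-X-Y at elevation 0 or 180 deg.  Frames inside a
guard band around the degeneracy are flagged and, in the series API,
linearly interpolated from their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DOF_NAMES",
    "THORACOHUMERAL_NAMES",
    "JointKinematicsSeries",
    "euler_yxz",
    "euler_yxy",
    "ac_displacement",
    "unwrap_degrees",
    "angle_unwrap_and_reference",
]

#: Outcome degree-of-freedom order used throughout the package (Table-style):
#: three AC rotations (deg) then three AC displacements (mm).
DOF_NAMES: tuple[str, ...] = (
    "retraction_protraction",
    "lateral_medial_rotation",
    "anterior_posterior_tilt",
    "superior_inferior",
    "anterior_posterior",
    "lateral_medial",
)

THORACOHUMERAL_NAMES: tuple[str, ...] = ("plane_of_elevation", "elevation", "axial_rotation")

#: Guard band on the degenerate trigonometric pivot (cos for Y-X-Z, sin for Y-X-Y).
GIMBAL_TOL = 1e-6


@dataclass
class JointKinematicsSeries:
    """Per-frame joint kinematics of one trial.

    ``ac`` holds the six AC DOFs in :data:`DOF_NAMES` order (deg, deg, deg,
    mm, mm, mm); ``thoracohumeral`` the three Y-X-Y humerus-thorax angles
    (deg); ``gimbal`` flags frames whose Euler decomposition sat inside the
    degeneracy guard band (values there are interpolated).
    """

    time: np.ndarray
    ac: np.ndarray
    thoracohumeral: np.ndarray
    gimbal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ac = np.asarray(self.ac, dtype=float)
        self.thoracohumeral = np.asarray(self.thoracohumeral, dtype=float)
        n = len(self.time)
        if self.ac.shape != (n, 6):
            raise ValueError(f"ac must be (n, 6); got {self.ac.shape} for n={n}")
        if self.thoracohumeral.shape != (n, 3):
            raise ValueError("thoracohumeral must be (n, 3)")
        if self.gimbal is None:
            self.gimbal = np.zeros(n, dtype=bool)
        self.gimbal = np.asarray(self.gimbal, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def elevation(self) -> np.ndarray:
        """Thoracohumeral elevation angle trace (deg)."""
        return self.thoracohumeral[:, 1]


def _interpolate_flagged(values: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Linearly interpolate flagged rows from unflagged neighbours."""
    if not flagged.any():
        return values
    if flagged.all():
        raise ValueError("every frame is inside the gimbal guard band")
    out = values.copy()
    idx = np.arange(len(values))
    good = ~flagged
    for c in range(values.shape[1]):
        out[flagged, c] = np.interp(idx[flagged], idx[good], values[good, c])
    return out


def euler_yxz(R: np.ndarray, degrees: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Mobile Y-X-Z Euler angles of rotation matrices ``R = Ry(a) Rx(b) Rz(c)``.

    Accepts (3, 3) or (n, 3, 3); returns (..., 3) angles and a (...,) gimbal
    flag (second angle within the guard band of +/-90 deg, where the first
    and third axes align and the decomposition is ill-posed).
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    R = R[None] if single else R
    sb = np.clip(-R[:, 1, 2], -1.0, 1.0)
    cb = np.sqrt(np.maximum(0.0, 1.0 - sb**2))
    flag = cb < GIMBAL_TOL
    b = np.arcsin(sb)
    a = np.arctan2(R[:, 0, 2], R[:, 2, 2])
    c = np.arctan2(R[:, 1, 0], R[:, 1, 1])
    # at the degeneracy only a +/- c is defined; attribute it to the first axis
    if flag.any():
        a_lock = np.arctan2(-sb * R[:, 2, 0], R[:, 0, 0])
        a = np.where(flag, a_lock, a)
        c = np.where(flag, 0.0, c)
    ang = np.stack([a, b, c], axis=-1)
    if degrees:
        ang = np.degrees(ang)
    return (ang[0], flag[0]) if single else (ang, flag)


def euler_yxy(R: np.ndarray, degrees: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Mobile Y-X-Y Euler angles ``R = Ry(plane) Rx(elevation) Ry(axial)``.

    Degenerate at elevation 0 and 180 deg; there the plane of elevation is
    undefined and, by the continuity convention, reported as 0 with the full
    Y rotation attributed to the axial angle (so the identity maps to
    (0, 0, 0)).
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    R = R[None] if single else R
    cb = np.clip(R[:, 1, 1], -1.0, 1.0)
    sb = np.sqrt(np.maximum(0.0, 1.0 - cb**2))
    flag = sb < GIMBAL_TOL
    b = np.arccos(cb)
    a = np.arctan2(R[:, 0, 1], R[:, 2, 1])
    c = np.arctan2(R[:, 1, 0], -R[:, 1, 2])
    if flag.any():
        c_lock = np.arctan2(R[:, 0, 2], R[:, 0, 0])
        a = np.where(flag, 0.0, a)
        c = np.where(flag, c_lock, c)
    ang = np.stack([a, b, c], axis=-1)
    if degrees:
        ang = np.degrees(ang)
    return (ang[0], flag[0]) if single else (ang, flag)


def compose_yxz(a: float, b: float, c: float, degrees: bool = True) -> np.ndarray:
    """Rotation matrix ``Ry(a) Rx(b) Rz(c)`` (inverse of :func:`euler_yxz`)."""
    if degrees:
        a, b, c = np.radians([a, b, c])
    return _ry(a) @ _rx(b) @ _rz(c)


def compose_yxy(a: float, b: float, c: float, degrees: bool = True) -> np.ndarray:
    """Rotation matrix ``Ry(a) Rx(b) Ry(c)`` (inverse of :func:`euler_yxy`)."""
    if degrees:
        a, b, c = np.radians([a, b, c])
    return _ry(a) @ _rx(b) @ _ry(c)


def _rx(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def ac_displacement(p_dorsal_lab: np.ndarray, clavicle_frames) -> np.ndarray:
    """Express the dorsal acromial point along the AC joint (clavicle) axes.

    Returns (n, 3) components in DOF order superior_inferior (+Y),
    anterior_posterior (+X), lateral_medial (+Z); raw values, mm -- the
    zero-referencing to the intact resting posture happens in the outcome
    reduction.
    """
    p = np.asarray(p_dorsal_lab, dtype=float)
    origins = np.asarray(clavicle_frames.origin)
    if p.ndim == 2 and origins.ndim == 2 and len(p) != len(origins):
        raise ValueError("point series and frame series length mismatch")
    local = clavicle_frames.to_local(p)
    if local.ndim == 1:
        local = local[None]
    return np.stack([local[..., 1], local[..., 0], local[..., 2]], axis=-1)


def unwrap_degrees(angles: np.ndarray, axis: int = 0) -> np.ndarray:
    """360-degree unwrap along ``axis`` (idempotent on continuous traces)."""
    return np.unwrap(np.asarray(angles, dtype=float), axis=axis, period=360.0)


def angle_unwrap_and_reference(
    series: JointKinematicsSeries,
    reference: np.ndarray | None = None,
) -> JointKinematicsSeries:
    """Unwrap the rotational traces and optionally subtract a reference posture.

    ``reference`` is a 6-vector in :data:`DOF_NAMES` order (typically the
    series values at a declared reference frame); displacement DOFs are
    referenced by plain subtraction, rotations after unwrapping.
    """
    ac = series.ac.copy()
    ac[:, :3] = unwrap_degrees(ac[:, :3])
    th = unwrap_degrees(series.thoracohumeral.copy())
    if reference is not None:
        ac = ac - np.asarray(reference, dtype=float).reshape(6)
    return JointKinematicsSeries(series.time, ac, th, series.gimbal.copy())
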