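"""ISB anatomical coordinate systems for the shoulder girdle.

Conventions (right shoulder; lab X anterior, Y superior, Z to the right):

* thorax   -- origin IJ; Y from mid(PX, T8) toward mid(IJ, C7); Z normal to
  the IJ/C7/mid(PX,T8) plane pointing right; X = Y × Z pointing forward.
* clavicle -- origin SC; Z from SC to AC (lateral); X forward, perpendicular
  to Z and the thorax Y; Y = Z × X.  Axial rotation of the clavicle is not
  observable from SC/AC alone, so the anatomical frame is defined at the
  reference posture and then carried by the tracked 6-DOF cluster pose.
* scapula  -- origin AA; Z from TS to AA; X normal to the AI/AA/TS plane
  pointing forward; Y = Z × X.
* humerus  -- origin GH; Y from mid(EL, EM) to GH; X normal to the
  GH/EL/EM plane pointing forward; Z = X × Y.

All constructors accept either single points (3,) or stacked trajectories
(n, 3) and return axes as rotation matrices with the axes in columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoneCoordinateSystem",
    "thorax_frame",
    "clavicle_frame",
    "scapula_frame",
    "humerus_frame",
]

_DEGENERATE_TOL = 1e-10


@dataclass(frozen=True)
class BoneCoordinateSystem:
    """Anatomical frame(s): ``origin`` (..., 3) and ``axes`` (..., 3, 3).

    ``axes[..., :, i]`` is the i-th unit axis (columns X, Y, Z); the matrix
    is the rotation taking anatomical-frame coordinates to the lab frame.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if axes.shape[-2:] != (3, 3):
            raise ValueError("axes must be (..., 3, 3)")
        gram = np.einsum("...ji,...jk->...ik", axes, axes)
        if np.abs(gram - np.eye(3)).max() > 1e-8:
            raise ValueError("axes are not orthonormal")
        if np.abs(np.linalg.det(axes) - 1.0).max() > 1e-8:
            raise ValueError("axes are not right-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @property
    def x(self) -> np.ndarray:
        return self.axes[..., :, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[..., :, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[..., :, 2]

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express lab points (..., 3) in this frame."""
        rel = np.asarray(points, dtype=float) - self.origin
        return np.einsum("...ji,...j->...i", self.axes, rel)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n <= _DEGENERATE_TOL):
        raise ValueError(f"degenerate landmark configuration: {what}")
    return v / n


def _stack_axes(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    return np.stack([x, y, z], axis=-1)


def thorax_frame(IJ, C7, PX, T8) -> BoneCoordinateSystem:
    """ISB thorax frame from the four thoracic landmarks."""
    IJ, C7, PX, T8 = (np.asarray(p, dtype=float) for p in (IJ, C7, PX, T8))
    upper = 0.5 * (IJ + C7)
    lower = 0.5 * (PX + T8)
    y = _unit(upper - lower, "thorax Y (spine midpoints coincide)")
    # plane of IJ, C7 and the lower midpoint; normal points to the right
    z0 = _unit(np.cross(C7 - IJ, lower - IJ), "thorax plane (collinear landmarks)")
    x = _unit(np.cross(y, z0), "thorax X")
    z = np.cross(x, y)
    return BoneCoordinateSystem(IJ, _stack_axes(x, y, z))


def clavicle_frame(SC, AC, thorax_y) -> BoneCoordinateSystem:
    """ISB clavicle frame; ``thorax_y`` resolves the axial indeterminacy."""
    SC, AC = np.asarray(SC, dtype=float), np.asarray(AC, dtype=float)
    z = _unit(AC - SC, "clavicle Z (SC == AC)")
    x = _unit(np.cross(np.asarray(thorax_y, dtype=float), z), "clavicle X (Z parallel thorax Y)")
    y = np.cross(z, x)
    return BoneCoordinateSystem(SC, _stack_axes(x, y, z))


def scapula_frame(AA, TS, AI) -> BoneCoordinateSystem:
    """ISB scapula frame from the acromial angle, trigonum spinae and inferior angle."""
    AA, TS, AI = (np.asarray(p, dtype=float) for p in (AA, TS, AI))
    z = _unit(AA - TS, "scapula Z (AA == TS)")
    x = _unit(np.cross(AA - AI, z), "scapula X (collinear landmarks)")
    y = np.cross(z, x)
    return BoneCoordinateSystem(AA, _stack_axes(x, y, z))


def humerus_frame(GH, EL, EM) -> BoneCoordinateSystem:
    """ISB humerus frame (option with the elbow epicondyle axis)."""
    GH, EL, EM = (np.asarray(p, dtype=float) for p in (GH, EL, EM))
    y = _unit(GH - 0.5 * (EL + EM), "humerus Y (GH at elbow midpoint)")
    x = _unit(np.cross(y, EL - EM), "humerus X (collinear landmarks)")
    z = np.cross(x, y)
    return BoneCoordinateSystem(GH, _stack_axes(x, y, z))
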