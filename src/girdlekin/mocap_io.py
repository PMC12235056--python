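"""File formats and study metadata.

The pipeline reads marker trajectories from C3D or from Qualisys-style TSV
exports, normalises everything to millimetres at a declared sample rate, and
writes per-trial kinematics and study-level outcomes as long-format CSV.
Occlusions live in an explicit per-marker/per-frame visibility mask; in the
TSV dialect an occluded sample is encoded as the ``0 0 0`` triplet, which the
reader converts to a mask entry rather than a position at the origin.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _c3d

__all__ = [
    "MOTION_TYPES",
    "CONDITIONS",
    "GROUPS",
    "SIDES",
    "MarkerTrajectorySet",
    "StudyMetadata",
    "read_c3d",
    "write_c3d",
    "read_marker_tsv",
    "write_marker_tsv",
    "write_kinematics_csv",
    "write_outcomes_csv",
]

MOTION_TYPES = (
    "flexion",
    "abduction",
    "internal_external_rotation",
    "horizontal_abduction",
    "vertical_traction",
    "horizontal_compression",
)

CONDITIONS = (
    "intact",
    "rockwood5",
    "cc_only",
    "construct1",
    "construct2",
    "construct3",
    "construct4",
)

GROUPS = ("AC_first", "CC_first")
SIDES = ("left", "right")

#: Fixed outcome column order (rotations then displacements).
DOF_COLUMNS = (
    "retraction_protraction",
    "lateral_medial_rotation",
    "anterior_posterior_tilt",
    "superior_inferior",
    "anterior_posterior",
    "lateral_medial",
)


@dataclass
class MarkerTrajectorySet:
    """Time-indexed 3D marker positions in the laboratory frame (mm).

    ``positions`` is (n_frames, n_markers, 3); ``mask`` is True where the
    marker was visible.  Positions must be finite wherever visible; occluded
    samples are stored as NaN.
    """

    sample_rate: float
    labels: list[str]
    positions: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(f"positions must be (frames, markers, 3), got {self.positions.shape}")
        if self.positions.shape[1] != len(self.labels):
            raise ValueError("label count does not match marker axis")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.positions.shape[:2]:
            raise ValueError("mask shape must be (frames, markers)")
        if not np.isfinite(self.positions[self.mask]).all():
            raise ValueError("non-finite position at a visible sample")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    def frame_dict(self, frame: int) -> dict[str, np.ndarray]:
        """Visible markers of one frame as a label -> position mapping."""
        return {
            l: self.positions[frame, j]
            for j, l in enumerate(self.labels)
            if self.mask[frame, j]
        }


@dataclass(frozen=True)
class StudyMetadata:
    """Identity of one trial within the study design.

    In the cadaveric design the surgical-sequence group is tied to the side
    (left shoulders AC-first, right shoulders CC-first); synthetic datasets
    may break that pairing by passing ``enforce_side_group=False``.
    """

    shoulder: str
    side: str
    group: str
    condition: str
    motion_type: str
    cycle: int = 1
    enforce_side_group: bool = True

    def __post_init__(self) -> None:
        for value, allowed, what in (
            (self.side, SIDES, "side"),
            (self.group, GROUPS, "group"),
            (self.condition, CONDITIONS, "condition"),
            (self.motion_type, MOTION_TYPES, "motion_type"),
        ):
            if value not in allowed:
                raise ValueError(f"invalid {what} '{value}' (allowed: {allowed})")
        if self.enforce_side_group:
            expected = "AC_first" if self.side == "left" else "CC_first"
            if self.group != expected:
                raise ValueError(
                    f"study design pairs side={self.side} with group={expected}; "
                    "pass enforce_side_group=False to override"
                )


# ----------------------------------------------------------------- C3D


def read_c3d(path) -> MarkerTrajectorySet:
    """Read a C3D file; positions are normalised to millimetres."""
    content = _c3d.read(path)
    scale = 1000.0 if content.units.lower() in ("m", "meter", "metre") else 1.0
    positions = content.points * scale
    return MarkerTrajectorySet(
        sample_rate=content.rate,
        labels=content.labels,
        positions=positions,
        mask=content.valid,
    )


def write_c3d(path, traj: MarkerTrajectorySet) -> None:
    """Write a C3D file (float32 storage; sub-micrometre truncation)."""
    _c3d.write(
        path,
        _c3d.C3DContent(
            labels=list(traj.labels),
            rate=float(traj.sample_rate),
            points=traj.positions,
            valid=traj.mask,
            units="mm",
        ),
    )


# ----------------------------------------------------------------- TSV


def read_marker_tsv(path) -> MarkerTrajectorySet:
    """Read a Qualisys-style tab-separated marker export.

    Header keys (NO_OF_FRAMES, NO_OF_MARKERS, FREQUENCY, MARKER_NAMES, ...)
    precede a frame-per-row numeric block of x/y/z triplets.  ``0 0 0``
    triplets and blank cells are occlusions.
    """
    header: dict[str, list[str]] = {}
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            cells = line.rstrip("\r\n").split("\t")
            if not cells or cells == [""]:
                continue
            key = cells[0].upper()
            if key and not _is_number(cells[0]):
                header[key] = cells[1:]
            else:
                rows.append(cells)
    if "FREQUENCY" not in header:
        raise ValueError(f"{path}: missing FREQUENCY header")
    rate = float(header["FREQUENCY"][0])
    labels = header.get("MARKER_NAMES")
    if not labels:
        raise ValueError(f"{path}: missing MARKER_NAMES header")
    labels = [l for l in labels if l]
    n_markers = len(labels)
    if "NO_OF_MARKERS" in header and int(header["NO_OF_MARKERS"][0]) != n_markers:
        raise ValueError(f"{path}: NO_OF_MARKERS disagrees with MARKER_NAMES")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    positions = np.full((len(rows), n_markers, 3), np.nan)
    for i, cells in enumerate(rows):
        if len(cells) < 3 * n_markers:
            raise ValueError(f"{path}: row {i} has {len(cells)} cells, needs {3 * n_markers}")
        for j in range(n_markers):
            trip = cells[3 * j : 3 * j + 3]
            if any(c.strip() == "" for c in trip):
                continue
            xyz = [float(c) for c in trip]
            if xyz == [0.0, 0.0, 0.0]:
                continue  # Qualisys occlusion encoding
            positions[i, j] = xyz
    mask = np.isfinite(positions).all(axis=2)
    if "NO_OF_FRAMES" in header and int(header["NO_OF_FRAMES"][0]) != len(rows):
        raise ValueError(f"{path}: NO_OF_FRAMES disagrees with data rows")
    return MarkerTrajectorySet(sample_rate=rate, labels=labels, positions=positions, mask=mask)


def write_marker_tsv(path, traj: MarkerTrajectorySet, decimals: int = 9) -> None:
    """Write the Qualisys-style TSV dialect (occlusions as ``0 0 0``)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"NO_OF_FRAMES\t{traj.n_frames}\n")
        fh.write(f"NO_OF_CAMERAS\t11\n")
        fh.write(f"NO_OF_MARKERS\t{traj.n_markers}\n")
        fh.write(f"FREQUENCY\t{traj.sample_rate:g}\n")
        fh.write("NO_OF_ANALOG\t0\n")
        fh.write("ANALOG_FREQUENCY\t0\n")
        fh.write("DATA_INCLUDED\t3D\n")
        fh.write("MARKER_NAMES\t" + "\t".join(traj.labels) + "\n")
        fmt = f"%.{decimals}f"
        out = np.where(traj.mask[:, :, None], traj.positions, 0.0)
        np.savetxt(fh, out.reshape(traj.n_frames, -1), fmt=fmt, delimiter="\t")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ----------------------------------------------------------------- CSV outputs


def write_kinematics_csv(series, metadata: StudyMetadata, path) -> None:
    """Per-trial long-format kinematics CSV (one row per frame)."""
    df = kinematics_frame(series, metadata)
    df.to_csv(path, index=False)


def kinematics_frame(series, metadata: StudyMetadata) -> pd.DataFrame:
    from .joints import THORACOHUMERAL_NAMES  # local import to avoid a cycle

    data = {
        "shoulder": metadata.shoulder,
        "side": metadata.side,
        "group": metadata.group,
        "condition": metadata.condition,
        "motion_type": metadata.motion_type,
        "cycle": metadata.cycle,
        "frame": np.arange(series.n_frames),
        "time_s": series.time,
    }
    for k, name in enumerate(DOF_COLUMNS):
        data[name] = series.ac[:, k]
    for k, name in enumerate(THORACOHUMERAL_NAMES):
        data[name] = series.thoracohumeral[:, k]
    data["gimbal_flag"] = series.gimbal.astype(int)
    return pd.DataFrame(data)


def write_outcomes_csv(table: pd.DataFrame, path) -> None:
    """Study-level outcome table CSV with the fixed DOF column order."""
    meta_cols = [c for c in ("shoulder", "side", "group", "condition") if c in table.columns]
    dof_cols = [c for c in table.columns if c not in meta_cols]
    ordered = meta_cols + sorted(
        dof_cols,
        key=lambda c: next(
            (i for i, d in enumerate(DOF_COLUMNS) if c.endswith(d)), len(DOF_COLUMNS)
        ),
    )
    table.loc[:, ordered].to_csv(path, index=False)
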