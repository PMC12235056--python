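"""End-to-end orchestration: markers in, outcome table out.

``process_trial`` runs one trial through the full measurement chain --
optional mirroring of left shoulders into the right-shoulder convention,
gap filling, zero-phase low-pass filtering, cluster pose estimation,
CT-anatomy fusion, ISB frame construction and AC/thoracohumeral joint
kinematics.  ``process_study`` maps a synthetic (or loaded) study through
it and reduces the per-trial kinematics to the outcome table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .frames import clavicle_frame, humerus_frame, scapula_frame, thorax_frame, BoneCoordinateSystem
from .joints import (
    JointKinematicsSeries,
    _interpolate_flagged,
    ac_displacement,
    euler_yxy,
    euler_yxz,
    unwrap_degrees,
)
from .mocap_io import MarkerTrajectorySet, StudyMetadata
from .outcomes import build_outcome_table
from .preprocess import DEFAULT_CUTOFF_HZ, DEFAULT_FILTER_ORDER, DEFAULT_MAX_GAP_S, fill_gaps, lowpass
from .rigid import estimate_pose_series, landmark_trajectory, mirror_points, register_ct
from .synth import SEGMENTS, SkeletonModel, StudyDataset, mirror_skeleton

__all__ = ["mirror_left_to_right", "process_trial", "process_study"]


def mirror_left_to_right(
    traj: MarkerTrajectorySet, skeleton: SkeletonModel, side: str
) -> tuple[MarkerTrajectorySet, SkeletonModel]:
    """Reflect a left shoulder's markers and CT anatomy into the right-side
    convention (applying it twice is the identity; right sides are rejected).
    """
    if side != "left":
        raise ValueError(f"mirroring applies to left shoulders, got side='{side}'")
    mirrored = MarkerTrajectorySet(
        sample_rate=traj.sample_rate,
        labels=list(traj.labels),
        positions=mirror_points(traj.positions),
        mask=traj.mask.copy(),
    )
    return mirrored, mirror_skeleton(skeleton)


def process_trial(
    traj: MarkerTrajectorySet,
    skeleton: SkeletonModel,
    side: str = "right",
    filter_markers: bool = True,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    filter_order: int = DEFAULT_FILTER_ORDER,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> JointKinematicsSeries:
    """Full kinematics chain for one trial.

    Returns the per-frame AC joint series (rotations deg, raw displacements
    mm) and thoracohumeral angles; rotational traces are unwrapped and
    gimbal-flagged frames interpolated from their neighbours.
    """
    if side == "left":
        traj, skeleton = mirror_left_to_right(traj, skeleton, side)
    if not traj.mask.all():
        traj = fill_gaps(traj, max_gap_s=max_gap_s)
    if filter_markers:
        traj = lowpass(traj, order=filter_order, cutoff_hz=cutoff_hz)

    lab_landmarks: dict[str, dict[str, np.ndarray]] = {}
    for seg in SEGMENTS:
        model = skeleton.clusters[seg]
        anatomy = skeleton.anatomies[seg]
        reg, _ = register_ct(anatomy, model)
        R, t, _ = estimate_pose_series(model, traj.positions, traj.mask, traj.labels)
        pts = dict(anatomy.landmarks)
        if anatomy.p_dorsal is not None:
            pts = {**pts, "P_dorsal": anatomy.p_dorsal}
        lab_landmarks[seg] = {
            name: landmark_trajectory(p, reg, R, t) for name, p in pts.items()
        }

    th = lab_landmarks["thorax"]
    thor = thorax_frame(th["IJ"], th["C7"], th["PX"], th["T8"])
    cl = lab_landmarks["clavicle"]
    clav = clavicle_frame(cl["SC"], cl["AC"], thor.y)
    sc = lab_landmarks["scapula"]
    scap = scapula_frame(sc["AA"], sc["TS"], sc["AI"])
    hu = lab_landmarks["humerus"]
    hum = humerus_frame(hu["GH"], hu["EL"], hu["EM"])

    R_ac = np.einsum("nji,njk->nik", clav.axes, scap.axes)
    ac_ang, flag_ac = euler_yxz(R_ac)
    disp = ac_displacement(sc["P_dorsal"], clav)
    R_th = np.einsum("nji,njk->nik", thor.axes, hum.axes)
    th_ang, flag_th = euler_yxy(R_th)

    ac_ang = unwrap_degrees(_interpolate_flagged(ac_ang, flag_ac))
    th_ang = unwrap_degrees(_interpolate_flagged(th_ang, flag_th))
    return JointKinematicsSeries(
        time=traj.time,
        ac=np.concatenate([ac_ang, disp], axis=1),
        thoracohumeral=th_ang,
        gimbal=flag_ac | flag_th,
    )


def process_study(
    dataset: StudyDataset,
    filter_markers: bool = True,
) -> pd.DataFrame:
    """Run every trial of a study and reduce to the outcome table.

    Each (shoulder, condition) cell needs its abduction trial for the
    resting alignment; all generated motions contribute to the cumulative
    range of motion.
    """
    cells: dict[tuple[str, str], dict] = {}
    meta: dict[str, dict[str, str]] = {}
    for trial in dataset.trials:
        m = trial.metadata
        meta[m.shoulder] = {"group": m.group, "side": m.side}
        series = process_trial(
            trial.trajectories, trial.skeleton, side=m.side, filter_markers=filter_markers
        )
        cell = cells.setdefault((m.shoulder, m.condition), {"motions": {}})
        cell["motions"][m.motion_type] = series
        if m.motion_type == "abduction":
            cell["abduction"] = series
    for key, cell in cells.items():
        if "abduction" not in cell:
            raise ValueError(f"cell {key} lacks the abduction trial needed for alignment")
    return build_outcome_table(
        cells,
        meta,
        n_cycles=dataset.config.n_cycles,
        expected_motions=tuple(dataset.config.motions),
    )
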