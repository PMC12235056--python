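"""Synthetic shoulder-girdle motion generator.

Emulates the measurement structure of a robot-driven whole-shoulder cadaver
experiment: a four-segment kinematic chain (thorax -> clavicle -> scapula ->
humerus) executes prescribed joint-angle waveforms for six standardised
motions, three raised-cosine cycles each, while four-marker clusters rigidly
attached to every segment are observed at 100 Hz with optional isotropic
Gaussian noise and occlusion gaps.  Surgical conditions are modelled as a
static alignment offset at the AC joint plus a per-DOF multiplier on the AC
motion amplitude (a stability scale).  Ground truth is stored alongside the
generated markers so every downstream stage has a known answer.

Alignment offsets are injected exactly: the rotational offset is a
rest-anchored premultiplier on the commanded AC orientation and the
translational offset a constant shift of the dorsal acromial point in the
(static) clavicle frame, so a condition trial's markers are a constant rigid
map of the intact trial's markers.  Linear stages (filtering) and the
equivariant pose estimator preserve that map exactly, which is what makes
zero-noise end-to-end recovery checks meaningful to machine precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import clavicle_frame, humerus_frame, scapula_frame, thorax_frame
from .joints import DOF_NAMES, compose_yxy, compose_yxz, euler_yxz
from .mocap_io import (
    CONDITIONS,
    GROUPS,
    MOTION_TYPES,
    MarkerTrajectorySet,
    StudyMetadata,
    write_c3d,
    write_marker_tsv,
)
from .rigid import BoneAnatomy, ClusterModel, RigidTransform, mirror_anatomy, mirror_points

__all__ = [
    "SEGMENTS",
    "SkeletonModel",
    "MotionWaveform",
    "ConditionScenario",
    "SyntheticTrial",
    "StudyConfig",
    "StudyDataset",
    "default_skeleton",
    "default_waveforms",
    "mirror_skeleton",
    "default_study_config",
    "generate_trial",
    "generate_study",
    "sample_alignment_offsets",
    "write_study",
]

SEGMENTS = ("thorax", "clavicle", "scapula", "humerus")

#: Intact resting AC orientation (retraction-protraction, lateral-medial
#: rotation, anterior-posterior tilt; deg) emulating typical scapula-on-
#: clavicle posture.
REST_AC_ANGLES = (59.1, 2.3, 7.7)


# ------------------------------------------------------------------ skeleton


@dataclass(frozen=True)
class SkeletonModel:
    """CT-frame anatomy, cluster models and ground-truth registrations."""

    anatomies: dict[str, BoneAnatomy]
    clusters: dict[str, ClusterModel]
    registrations: dict[str, RigidTransform]  # CT frame -> technical frame

    def marker_positions_ct(self, segment: str) -> tuple[list[str], np.ndarray]:
        mk = self.anatomies[segment].markers
        labels = list(mk)
        return labels, np.array([mk[l] for l in labels])


#: Four-marker plate, ~80 mm across, non-coplanar by 12 mm (plate-local mm).
_PLATE = np.array(
    [
        [0.0, 0.0, 0.0],
        [80.0, 0.0, 0.0],
        [64.0, 56.0, 12.0],
        [12.0, 60.0, -10.0],
    ]
)

#: Right-shoulder CT-frame landmark coordinates (mm; X anterior, Y superior,
#: Z right; thorax origin at the incisura jugularis).
_LANDMARKS: dict[str, dict[str, tuple[float, float, float]]] = {
    "thorax": {
        "IJ": (0.0, 0.0, 0.0),
        "C7": (-70.0, 15.0, 0.0),
        "PX": (10.0, -150.0, 0.0),
        "T8": (-90.0, -140.0, 0.0),
    },
    "clavicle": {
        "SC": (5.0, 0.0, 20.0),
        "AC": (15.0, 30.0, 160.0),
    },
    "scapula": {
        "AA": (-15.0, 25.0, 175.0),
        "TS": (-110.0, 10.0, 80.0),
        "AI": (-100.0, -110.0, 90.0),
    },
    "humerus": {
        "GH": (5.0, 5.0, 190.0),
        "EL": (12.0, -280.0, 205.0),
        "EM": (4.0, -285.0, 172.0),
    },
}

_P_DORSAL = (-38.0, 28.0, 168.0)

#: Plate placement per segment: small rotation (deg, about lab Y) + offset.
_PLATE_POSE: dict[str, tuple[float, tuple[float, float, float]]] = {
    "thorax": (5.0, (30.0, -60.0, -40.0)),
    "clavicle": (-10.0, (20.0, 25.0, 80.0)),
    "scapula": (20.0, (-70.0, -20.0, 120.0)),
    "humerus": (35.0, (15.0, -120.0, 195.0)),
}


def default_skeleton() -> SkeletonModel:
    """Build the canonical right-shoulder skeleton with cluster plates."""
    anatomies: dict[str, BoneAnatomy] = {}
    clusters: dict[str, ClusterModel] = {}
    registrations: dict[str, RigidTransform] = {}
    for seg in SEGMENTS:
        ang, offset = _PLATE_POSE[seg]
        t = np.radians(ang)
        R = np.array(
            [[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]]
        )
        place = RigidTransform(R, np.array(offset))
        markers_ct = place.apply(_PLATE)
        labels = [f"{seg}_m{i + 1}" for i in range(len(_PLATE))]
        anatomies[seg] = BoneAnatomy(
            bone=seg,
            landmarks=_LANDMARKS[seg],
            markers=dict(zip(labels, markers_ct)),
            p_dorsal=_P_DORSAL if seg == "scapula" else None,
        )
        # technical frame := plate-local frame; registration maps CT -> technical
        clusters[seg] = ClusterModel(segment=seg, positions=dict(zip(labels, _PLATE)))
        registrations[seg] = place.inverse()
    return SkeletonModel(anatomies, clusters, registrations)


# ------------------------------------------------------------------ waveforms


@dataclass(frozen=True)
class MotionWaveform:
    """Prescribed waveform of one standardised motion.

    All DOF traces are raised-cosine cycles ``rest + A * (1 - cos)/2`` --
    smooth everywhere (continuous first derivative), starting and ending at
    the rest value, with peak excursion ``A`` (so peak-to-peak range equals
    ``|A|``).  A rest hold of ``hold_s`` seconds precedes the first cycle,
    separates consecutive cycles and follows the last one, emulating the
    robot pausing at the resting posture between repetitions; the resting
    posture is therefore held as a quiescent plateau rather than touched
    for a single sample.  ``ac_amplitude`` follows :data:`DOF_NAMES` order
    (deg, deg, deg, mm, mm, mm); ``humerus_rest``/``humerus_amplitude``
    drive the thoracohumeral plane of elevation, elevation and axial
    rotation (deg).
    """

    motion_type: str
    cycle_s: float = 3.0
    hold_s: float = 1.5
    n_cycles: int = 3
    ac_amplitude: tuple = (0.0,) * 6
    humerus_rest: tuple = (0.0, 15.0, 0.0)
    humerus_amplitude: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.motion_type not in MOTION_TYPES:
            raise ValueError(f"unknown motion_type '{self.motion_type}'")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_s <= 0 or self.hold_s < 0:
            raise ValueError("cycle_s must be positive and hold_s non-negative")
        for tup, n in ((self.ac_amplitude, 6), (self.humerus_rest, 3), (self.humerus_amplitude, 3)):
            arr = np.asarray(tup, dtype=float)
            if arr.shape != (n,) or not np.isfinite(arr).all():
                raise ValueError(f"waveform parameter must be {n} finite values, got {tup}")

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.cycle_s + (self.n_cycles + 1) * self.hold_s

    def raised_cosine(self, t: np.ndarray) -> np.ndarray:
        """Unit profile in [0, 1]: one raised-cosine hump per cycle, zero in holds."""
        t = np.asarray(t, dtype=float)
        block = self.cycle_s + self.hold_s
        local = t - self.hold_s
        k = np.clip(np.floor(local / block), 0, self.n_cycles - 1)
        u = local - k * block
        in_cycle = (local >= 0) & (u >= 0) & (u <= self.cycle_s)
        return np.where(in_cycle, 0.5 * (1.0 - np.cos(2.0 * np.pi * u / self.cycle_s)), 0.0)


def default_waveforms(
    cycle_s: float = 3.0, hold_s: float = 1.5, n_cycles: int = 3
) -> dict[str, MotionWaveform]:
    """Study-condition waveforms for the six standardised motions.

    Amplitudes are package defaults (the experimental protocol used
    specimen-specific ranges): a few degrees of scapula-on-clavicle rotation
    and a few millimetres of translation per motion, with the humerus
    elevation sweeping 15-105 deg during abduction/flexion.  During
    abduction the AC displacement amplitudes are zero -- translational
    excursions are exercised by the traction and compression motions -- so
    the resting-alignment stage sees a translationally quiescent joint.
    """
    base = dict(cycle_s=cycle_s, hold_s=hold_s, n_cycles=n_cycles)
    return {
        "flexion": MotionWaveform(
            "flexion",
            ac_amplitude=(4.0, 3.0, 3.0, 1.5, 1.5, 1.0),
            humerus_rest=(80.0, 15.0, 0.0),
            humerus_amplitude=(0.0, 80.0, 0.0),
            **base,
        ),
        "abduction": MotionWaveform(
            "abduction",
            ac_amplitude=(5.0, 4.0, 4.0, 0.0, 0.0, 0.0),
            humerus_rest=(0.0, 15.0, 0.0),
            humerus_amplitude=(0.0, 90.0, 0.0),
            **base,
        ),
        "internal_external_rotation": MotionWaveform(
            "internal_external_rotation",
            ac_amplitude=(3.0, 2.0, 2.0, 1.0, 1.5, 0.5),
            humerus_rest=(0.0, 15.0, -25.0),
            humerus_amplitude=(0.0, 0.0, 50.0),
            **base,
        ),
        "horizontal_abduction": MotionWaveform(
            "horizontal_abduction",
            ac_amplitude=(4.0, 2.0, 3.0, 1.0, 2.0, 1.5),
            humerus_rest=(-20.0, 80.0, 0.0),
            humerus_amplitude=(70.0, 0.0, 0.0),
            **base,
        ),
        "vertical_traction": MotionWaveform(
            "vertical_traction",
            ac_amplitude=(1.0, 1.0, 1.0, 3.0, 1.0, 1.0),
            humerus_rest=(0.0, 12.0, 0.0),
            humerus_amplitude=(0.0, 6.0, 0.0),
            **base,
        ),
        "horizontal_compression": MotionWaveform(
            "horizontal_compression",
            ac_amplitude=(1.0, 1.0, 2.0, 1.0, 2.5, 2.0),
            humerus_rest=(0.0, 12.0, 0.0),
            humerus_amplitude=(10.0, 5.0, 0.0),
            **base,
        ),
    }


# ------------------------------------------------------------------ scenarios


@dataclass(frozen=True)
class ConditionScenario:
    """Surgical condition: static AC alignment offset + stability scaling.

    ``alignment_offset`` is condition-minus-intact in :data:`DOF_NAMES`
    order (deg/mm); ``stability_scale`` multiplies the per-DOF AC motion
    amplitude (values < 1 mean a stiffer, more stable joint).
    """

    condition: str
    group: str
    side: str
    alignment_offset: tuple = (0.0,) * 6
    stability_scale: tuple = (1.0,) * 6

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition '{self.condition}'")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group '{self.group}'")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side '{self.side}'")
        off = np.asarray(self.alignment_offset, dtype=float)
        sc = np.asarray(self.stability_scale, dtype=float)
        if off.shape != (6,) or not np.isfinite(off).all():
            raise ValueError("alignment_offset must be 6 finite values")
        if sc.shape != (6,) or not np.isfinite(sc).all() or (sc < 0).any():
            raise ValueError("stability_scale must be 6 finite non-negative values")
        if self.condition == "intact" and (np.any(off != 0) or np.any(sc != 1)):
            raise ValueError("intact scenario must have zero offset and unit stability scale")

    @classmethod
    def intact(cls, group: str = "CC_first", side: str = "right") -> "ConditionScenario":
        return cls("intact", group, side)


@dataclass
class SyntheticTrial:
    """One generated trial with its ground truth.

    ``ac_true`` holds the six commanded AC DOFs per frame: absolute Y-X-Z
    Euler angles (deg) and displacements *relative to the neutral resting
    geometry* (mm); ``d_rest_raw`` is the constant raw position of the
    dorsal acromial point in the clavicle frame, so the pipeline's raw
    displacement output equals ``ac_true[:, 3:] + d_rest_raw``.
    """

    metadata: StudyMetadata
    trajectories: MarkerTrajectorySet
    skeleton: SkeletonModel
    ac_true: np.ndarray
    thoracohumeral_true: np.ndarray
    d_rest_raw: np.ndarray
    sigma_mm: float
    seed: int | None
    waveform: MotionWaveform

    def expected_pipeline_ac(self) -> np.ndarray:
        """Ground truth on the raw scale the kinematics pipeline reports."""
        out = self.ac_true.copy()
        out[:, 3:] += self.d_rest_raw
        return out


def _dof_disp_to_xyz(d_dof: np.ndarray) -> np.ndarray:
    """(sup_inf, ant_post, lat_med) -> clavicle-frame (x, y, z)."""
    return np.stack([d_dof[..., 1], d_dof[..., 0], d_dof[..., 2]], axis=-1)


def generate_trial(
    skeleton: SkeletonModel,
    waveform: MotionWaveform,
    scenario: ConditionScenario,
    sigma_mm: float = 0.0,
    seed: int | None = None,
    sample_rate: float = 100.0,
    occlusions: list[tuple[str, float, float]] | None = None,
    rest_ac_angles: tuple = REST_AC_ANGLES,
    shoulder: str = "S01",
    cycle: int = 1,
) -> SyntheticTrial:
    """Generate marker trajectories for one motion under one joint condition.

    ``occlusions`` is a list of ``(marker_label, start_s, length_s)`` gaps
    blanked to NaN in the output.  With ``sigma_mm == 0`` and no occlusions
    the markers exactly satisfy the rigid cluster model at every frame.
    """
    if sigma_mm < 0 or not np.isfinite(sigma_mm):
        raise ValueError("sigma_mm must be finite and >= 0")
    n_frames = int(round(waveform.duration_s * sample_rate)) + 1
    t = np.arange(n_frames) / sample_rate
    profile = waveform.raised_cosine(t)

    anat = skeleton.anatomies
    # neutral anatomical frames in the CT(=lab-at-rest) frame
    th = anat["thorax"].landmarks
    thor = thorax_frame(th["IJ"], th["C7"], th["PX"], th["T8"])
    cl = anat["clavicle"].landmarks
    clav = clavicle_frame(cl["SC"], cl["AC"], thor.y)
    sc = anat["scapula"].landmarks
    scap = scapula_frame(sc["AA"], sc["TS"], sc["AI"])
    hum = humerus_frame(*(anat["humerus"].landmarks[k] for k in ("GH", "EL", "EM")))
    A_c, A_s, A_t, A_h = clav.axes, scap.axes, thor.axes, hum.axes

    amp = np.asarray(waveform.ac_amplitude, dtype=float) * np.asarray(
        scenario.stability_scale, dtype=float
    )
    offset = np.asarray(scenario.alignment_offset, dtype=float)

    # --- commanded AC orientation: intact wave, then rest-anchored offset
    rest = np.asarray(rest_ac_angles, dtype=float)
    ang_int = rest[None, :] + profile[:, None] * amp[None, :3]
    R_rest_int = compose_yxz(*rest)
    R_rest_cond = compose_yxz(*(rest + offset[:3]))
    G = R_rest_cond @ R_rest_int.T
    R_cmd = np.einsum(
        "ij,njk->nik", G, np.array([compose_yxz(*a) for a in ang_int])
    )
    ac_ang_true, _ = euler_yxz(R_cmd)

    # --- commanded AC displacement (relative to neutral) in DOF order
    d_dof = profile[:, None] * amp[None, 3:] + offset[None, 3:]
    p_d = anat["scapula"].p_dorsal
    d_rest_xyz = clav.to_local(p_d)  # neutral raw position of P_dorsal
    d_xyz = _dof_disp_to_xyz(d_dof) + d_rest_xyz

    # --- segment poses
    R_scap = np.einsum("ij,njk,lk->nil", A_c, R_cmd, A_s)
    p_d_lab = clav.origin + np.einsum("ij,nj->ni", A_c, d_xyz)
    t_scap = p_d_lab - np.einsum("nij,j->ni", R_scap, p_d)

    th_true = np.asarray(waveform.humerus_rest, dtype=float)[None, :] + profile[:, None] * np.asarray(
        waveform.humerus_amplitude, dtype=float
    )
    R_yxy = np.array([compose_yxy(*a) for a in th_true])
    R_hum = np.einsum("ij,njk,lk->nil", A_t, R_yxy, A_h)
    gh = anat["humerus"].landmarks["GH"]
    t_hum = gh - np.einsum("nij,j->ni", R_hum, gh)

    poses = {
        "thorax": (np.repeat(np.eye(3)[None], n_frames, axis=0), np.zeros((n_frames, 3))),
        "clavicle": (np.repeat(np.eye(3)[None], n_frames, axis=0), np.zeros((n_frames, 3))),
        "scapula": (R_scap, t_scap),
        "humerus": (R_hum, t_hum),
    }

    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for seg in SEGMENTS:
        seg_labels, m_ct = skeleton.marker_positions_ct(seg)
        R, tt = poses[seg]
        blocks.append(np.einsum("nij,mj->nmi", R, m_ct) + tt[:, None, :])
        labels.extend(seg_labels)
    positions = np.concatenate(blocks, axis=1)

    rng = np.random.default_rng(seed)
    if sigma_mm > 0:
        positions = positions + rng.normal(0.0, sigma_mm, size=positions.shape)

    mask = np.ones(positions.shape[:2], dtype=bool)
    if occlusions:
        for label, start_s, length_s in occlusions:
            if length_s >= waveform.duration_s:
                raise ValueError(f"occlusion of {length_s}s exceeds trial duration")
            if label not in labels:
                raise ValueError(f"occlusion references unknown marker '{label}'")
            j = labels.index(label)
            a = int(round(start_s * sample_rate))
            b = min(n_frames, a + int(round(length_s * sample_rate)))
            mask[a:b, j] = False
            positions[a:b, j] = np.nan

    side = scenario.side
    skel_out = skeleton
    if side == "left":
        positions = mirror_points(positions)
        skel_out = mirror_skeleton(skeleton)

    traj = MarkerTrajectorySet(
        sample_rate=sample_rate, labels=labels, positions=positions, mask=mask
    )
    meta = StudyMetadata(
        shoulder=shoulder,
        side=side,
        group=scenario.group,
        condition=scenario.condition,
        motion_type=waveform.motion_type,
        cycle=cycle,
        enforce_side_group=False,
    )
    d_rest_dof = np.array([d_rest_xyz[1], d_rest_xyz[0], d_rest_xyz[2]])
    return SyntheticTrial(
        metadata=meta,
        trajectories=traj,
        skeleton=skel_out,
        ac_true=np.concatenate([ac_ang_true, d_dof], axis=1),
        thoracohumeral_true=th_true,
        d_rest_raw=d_rest_dof,
        sigma_mm=sigma_mm,
        seed=seed,
        waveform=waveform,
    )


def mirror_skeleton(skeleton: SkeletonModel) -> SkeletonModel:
    """Reflect CT anatomy across the sagittal plane (cluster/tech frames follow)."""
    anatomies = {seg: mirror_anatomy(a) for seg, a in skeleton.anatomies.items()}
    clusters: dict[str, ClusterModel] = {}
    registrations: dict[str, RigidTransform] = {}
    S = np.diag([1.0, 1.0, -1.0])
    for seg, model in skeleton.clusters.items():
        # keep the technical frame attached to the mirrored plate: the
        # CT->technical map conjugates with the reflection, and the model
        # coordinates mirror with it, so registration still has det +1.
        clusters[seg] = ClusterModel(
            segment=seg, positions={k: S @ v for k, v in model.positions.items()}
        )
        reg = skeleton.registrations[seg]
        registrations[seg] = RigidTransform(S @ reg.rotation @ S, S @ reg.translation)
    return SkeletonModel(anatomies, clusters, registrations)


# ------------------------------------------------------------------ study


@dataclass(frozen=True)
class ScenarioSpec:
    """Population-level description of one condition within one group."""

    offset_median: tuple = (0.0,) * 6
    offset_iqr: tuple = (0.0,) * 6
    stability_scale: tuple = (1.0,) * 6


#: Alignment-offset medians (condition minus intact, DOF order) emulating the
#: study's reported effects; reconstruction conditions share the group-level
#: effect, the Rockwood lesion is group-independent.
_ROCKWOOD_OFFSET = (3.3, 1.8, 3.0, -8.7, 3.0, 6.3)
_AC_FIRST_OFFSET = (-1.9, 0.2, -10.1, -2.2, 0.8, 1.0)
_CC_FIRST_OFFSET = (-1.1, 2.1, -0.7, -3.7, 2.4, 2.3)

#: Between-shoulder dispersion (IQR of the alignment offset) per group;
#: levels chosen so the AC-first-minus-CC-first IQR differences match the
#: emulated study (-1.8, 0.9, -4.8, -1.5, 0.3, -3.4).
_AC_FIRST_IQR = (2.0, 3.0, 3.0, 2.0, 2.5, 1.6)
_CC_FIRST_IQR = (3.8, 2.1, 7.8, 3.5, 2.2, 5.0)
_ROCKWOOD_IQR = (3.0, 3.0, 3.0, 4.0, 3.0, 4.5)

_STABILITY_SCALE = {
    "intact": 1.0,
    "rockwood5": 2.5,
    "cc_only": 1.3,
    "construct1": 0.5,  # double vertical: stiffest construct
    "construct2": 0.8,
    "construct3": 0.9,
    "construct4": 0.7,
}


@dataclass(frozen=True)
class StudyConfig:
    """Design of a synthetic study (the defaults emulate the cadaver protocol)."""

    n_per_group: int = 5
    sigma_mm: float = 0.0
    motions: tuple = MOTION_TYPES
    cycle_s: float = 3.0
    hold_s: float = 1.5
    n_cycles: int = 3
    rest_ac_angles: tuple = REST_AC_ANGLES
    scenarios: dict[str, dict[str, ScenarioSpec]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 shoulders per group for the statistics")
        if not self.scenarios:
            object.__setattr__(self, "scenarios", _default_scenarios())
        for m in self.motions:
            if m not in MOTION_TYPES:
                raise ValueError(f"unknown motion '{m}'")


def _default_scenarios() -> dict[str, dict[str, ScenarioSpec]]:
    out: dict[str, dict[str, ScenarioSpec]] = {}
    for group in GROUPS:
        recon = _AC_FIRST_OFFSET if group == "AC_first" else _CC_FIRST_OFFSET
        iqr = _AC_FIRST_IQR if group == "AC_first" else _CC_FIRST_IQR
        specs = {
            "intact": ScenarioSpec(),
            "rockwood5": ScenarioSpec(
                _ROCKWOOD_OFFSET, _ROCKWOOD_IQR, (_STABILITY_SCALE["rockwood5"],) * 6
            ),
        }
        for cond in ("cc_only", "construct1", "construct2", "construct3", "construct4"):
            specs[cond] = ScenarioSpec(recon, iqr, (_STABILITY_SCALE[cond],) * 6)
        out[group] = specs
    return out


def default_study_config(**overrides) -> StudyConfig:
    return StudyConfig(**overrides)


def sample_alignment_offsets(
    spec: ScenarioSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-shoulder realised alignment offsets (n, 6).

    Between-shoulder variability is additive and logistic-distributed with
    scale ``IQR / (2 ln 3)`` (a logistic's IQR is ``2 s ln 3``), matching
    the medians/IQR summaries the outcomes stage reports.
    """
    med = np.asarray(spec.offset_median, dtype=float)
    iqr = np.asarray(spec.offset_iqr, dtype=float)
    scale = iqr / (2.0 * np.log(3.0))
    draws = np.where(
        scale[None, :] > 0,
        rng.logistic(0.0, np.where(scale > 0, scale, 1.0), size=(n, 6)),
        0.0,
    )
    return med[None, :] + draws


@dataclass
class StudyDataset:
    """All trials of a synthetic study plus a metadata table."""

    config: StudyConfig
    seed: int
    trials: list[SyntheticTrial]
    metadata: pd.DataFrame
    realized_offsets: pd.DataFrame

    def trial(self, shoulder: str, condition: str, motion: str) -> SyntheticTrial:
        for tr in self.trials:
            m = tr.metadata
            if (m.shoulder, m.condition, m.motion_type) == (shoulder, condition, motion):
                return tr
        raise KeyError(f"no trial for {shoulder}/{condition}/{motion}")


def generate_study(config: StudyConfig, seed: int) -> StudyDataset:
    """Generate the full synthetic study (deterministic for a fixed seed).

    Left shoulders form the AC-first group, right shoulders the CC-first
    group, mirroring the cadaveric design.  Realised per-shoulder condition
    offsets are drawn first, then each trial's marker noise uses a child
    seed, so the dataset is reproducible trial-by-trial.
    """
    rng = np.random.default_rng(seed)
    skeleton = default_skeleton()
    waveforms = default_waveforms(config.cycle_s, config.hold_s, config.n_cycles)

    shoulders = []
    for g, group in enumerate(GROUPS):
        side = "left" if group == "AC_first" else "right"
        for i in range(config.n_per_group):
            shoulders.append((f"{'L' if side == 'left' else 'R'}{i + 1:02d}", group, side))

    # realised offsets per shoulder x condition (drawn independently per cell)
    offset_rows = []
    realized: dict[tuple[str, str], np.ndarray] = {}
    for shoulder, group, side in shoulders:
        for cond in CONDITIONS:
            spec = config.scenarios[group][cond]
            off = sample_alignment_offsets(spec, 1, rng)[0]
            realized[(shoulder, cond)] = off
            offset_rows.append(
                {"shoulder": shoulder, "group": group, "side": side, "condition": cond}
                | {f"offset_{d}": off[k] for k, d in enumerate(DOF_NAMES)}
            )

    trials: list[SyntheticTrial] = []
    meta_rows = []
    child = np.random.SeedSequence(seed).spawn(len(shoulders) * len(CONDITIONS) * len(config.motions))
    idx = 0
    for shoulder, group, side in shoulders:
        for cond in CONDITIONS:
            spec = config.scenarios[group][cond]
            scenario = ConditionScenario(
                condition=cond,
                group=group,
                side=side,
                alignment_offset=tuple(realized[(shoulder, cond)]),
                stability_scale=tuple(spec.stability_scale),
            )
            for motion in config.motions:
                trial_seed = int(child[idx].generate_state(1)[0] % (2**31))
                idx += 1
                trial = generate_trial(
                    skeleton,
                    waveforms[motion],
                    scenario,
                    sigma_mm=config.sigma_mm,
                    seed=trial_seed,
                    rest_ac_angles=config.rest_ac_angles,
                    shoulder=shoulder,
                )
                trials.append(trial)
                meta_rows.append(
                    {
                        "shoulder": shoulder,
                        "side": side,
                        "group": group,
                        "condition": cond,
                        "motion_type": motion,
                        "n_cycles": config.n_cycles,
                        "seed": trial_seed,
                    }
                )
    return StudyDataset(
        config=config,
        seed=seed,
        trials=trials,
        metadata=pd.DataFrame(meta_rows),
        realized_offsets=pd.DataFrame(offset_rows),
    )


def write_study(dataset: StudyDataset, out_dir, fmt: str = "tsv", decimals: int = 9) -> None:
    """Write a study to disk: trials (TSV and/or C3D), metadata, ground truth.

    The directory receives one trajectory file per trial named
    ``<shoulder>_<condition>_<motion>.<ext>``, ``metadata.csv``,
    ``ground_truth.csv`` (per-frame commanded AC DOFs) and ``config.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt_frames = []
    for trial in dataset.trials:
        m = trial.metadata
        stem = f"{m.shoulder}_{m.condition}_{m.motion_type}"
        if fmt in ("tsv", "both"):
            write_marker_tsv(out / f"{stem}.tsv", trial.trajectories, decimals=decimals)
        if fmt in ("c3d", "both"):
            write_c3d(out / f"{stem}.c3d", trial.trajectories)
        gt = pd.DataFrame(trial.ac_true, columns=list(DOF_NAMES))
        gt.insert(0, "frame", np.arange(len(gt)))
        for key, val in (("shoulder", m.shoulder), ("condition", m.condition), ("motion_type", m.motion_type)):
            gt.insert(0, key, val)
        gt_frames.append(gt)
    dataset.metadata.to_csv(out / "metadata.csv", index=False)
    dataset.realized_offsets.to_csv(out / "realized_offsets.csv", index=False)
    pd.concat(gt_frames, ignore_index=True).to_csv(out / "ground_truth.csv", index=False)
    cfg = dataclasses.asdict(dataset.config)
    cfg["scenarios"] = {
        g: {c: dataclasses.asdict(s) for c, s in conds.items()}
        for g, conds in dataset.config.scenarios.items()
    }
    cfg["seed"] = dataset.seed
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=list))
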