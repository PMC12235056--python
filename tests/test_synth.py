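"""Synthetic generator: ground-truth consistency, determinism, noise, sides."""

import numpy as np
import pytest

import girdlekin as gk
from girdlekin.synth import (
    ConditionScenario,
    MotionWaveform,
    StudyConfig,
    sample_alignment_offsets,
    ScenarioSpec,
)


class TestGenerateTrial:
    def test_identity_waveform_gives_constant_markers_and_zero_truth(self, skeleton):
        wf = MotionWaveform("abduction")  # all amplitudes zero
        tr = gk.generate_trial(
            skeleton, wf, ConditionScenario.intact(), sigma_mm=0.0, rest_ac_angles=(0.0, 0.0, 0.0)
        )
        pos = tr.trajectories.positions
        assert np.abs(pos - pos[0]).max() < 1e-9
        assert np.abs(tr.ac_true).max() < 1e-9

    def test_markers_satisfy_rigid_cluster_model(self, abduction_trial):
        """With sigma=0 every frame is an exact rigid placement of the plate."""
        from girdlekin.rigid import estimate_pose_series

        traj = abduction_trial.trajectories
        for seg, model in abduction_trial.skeleton.clusters.items():
            _, _, rms = estimate_pose_series(model, traj.positions, traj.mask, traj.labels)
            assert rms.max() < 1e-9

    def test_pure_ac_rotation_recovered_downstream(self, skeleton):
        """A pure first-axis oscillation of 10 deg comes back on that DOF only."""
        wf = MotionWaveform("abduction", ac_amplitude=(10.0, 0, 0, 0, 0, 0),
                            humerus_rest=(0.0, 40.0, 0.0))
        tr = gk.generate_trial(skeleton, wf, ConditionScenario.intact(), sigma_mm=0.0,
                               rest_ac_angles=(0.0, 0.0, 0.0))
        series = gk.process_trial(tr.trajectories, tr.skeleton, filter_markers=False)
        assert series.ac[:, 0].max() == pytest.approx(10.0, abs=1e-9)
        assert series.ac[:, 0].min() == pytest.approx(0.0, abs=1e-9)
        assert np.abs(series.ac[:, 1:3]).max() < 1e-9
        assert np.abs(series.ac[:, 3:] - tr.d_rest_raw).max() < 1e-9

    def test_translation_offset_shifts_ground_truth_exactly(self, skeleton, waveforms):
        sc = ConditionScenario("rockwood5", "CC_first", "right",
                               alignment_offset=(0, 0, 0, -8.7, 0, 0),
                               stability_scale=(1.0,) * 6)
        tr = gk.generate_trial(skeleton, waveforms["abduction"], sc, sigma_mm=0.0)
        intact = gk.generate_trial(skeleton, waveforms["abduction"],
                                   ConditionScenario.intact(), sigma_mm=0.0)
        delta = tr.ac_true[:, 3] - intact.ac_true[:, 3]
        assert np.allclose(delta, -8.7, atol=1e-12)

    def test_occlusion_blanks_requested_span(self, skeleton, waveforms):
        tr = gk.generate_trial(
            skeleton, waveforms["abduction"], ConditionScenario.intact(),
            occlusions=[("scapula_m2", 2.0, 0.4)],
        )
        j = tr.trajectories.labels.index("scapula_m2")
        assert not tr.trajectories.mask[200:240, j].any()
        assert tr.trajectories.mask[:, j].sum() == tr.trajectories.n_frames - 40

    def test_occlusion_longer_than_trial_rejected(self, skeleton, waveforms):
        with pytest.raises(ValueError, match="duration"):
            gk.generate_trial(
                skeleton, waveforms["abduction"], ConditionScenario.intact(),
                occlusions=[("scapula_m2", 0.0, 99.0)],
            )

    def test_nonfinite_amplitude_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MotionWaveform("flexion", ac_amplitude=(np.nan, 0, 0, 0, 0, 0))


class TestNoiseAndSides:
    def test_angle_rmse_grows_monotonically_with_sigma(self, skeleton, waveforms):
        rmses = []
        for sigma in (0.0, 0.1, 0.5, 1.0):
            tr = gk.generate_trial(skeleton, waveforms["abduction"],
                                   ConditionScenario.intact(), sigma_mm=sigma, seed=11)
            series = gk.process_trial(tr.trajectories, tr.skeleton, filter_markers=False)
            err = series.ac[:, :3] - tr.ac_true[:, :3]
            rmses.append(float(np.sqrt(np.mean(err**2))))
        assert all(a < b for a, b in zip(rmses, rmses[1:]))

    def test_left_trial_matches_equivalent_right_trial(self, skeleton, waveforms):
        """After mirroring, left shoulders yield identical signed outcomes."""
        off = (3.3, 1.8, 3.0, -8.7, 3.0, 6.3)
        right = ConditionScenario("rockwood5", "CC_first", "right", alignment_offset=off,
                                  stability_scale=(2.5,) * 6)
        left = ConditionScenario("rockwood5", "AC_first", "left", alignment_offset=off,
                                 stability_scale=(2.5,) * 6)
        tr_r = gk.generate_trial(skeleton, waveforms["abduction"], right, sigma_mm=0.0)
        tr_l = gk.generate_trial(skeleton, waveforms["abduction"], left, sigma_mm=0.0)
        ser_r = gk.process_trial(tr_r.trajectories, tr_r.skeleton, side="right", filter_markers=False)
        ser_l = gk.process_trial(tr_l.trajectories, tr_l.skeleton, side="left", filter_markers=False)
        assert np.abs(ser_r.ac - ser_l.ac).max() < 1e-9

    def test_mirror_right_side_rejected(self, abduction_trial):
        from girdlekin.pipeline import mirror_left_to_right

        with pytest.raises(ValueError, match="left"):
            mirror_left_to_right(abduction_trial.trajectories, abduction_trial.skeleton, "right")


class TestGenerateStudy:
    def test_same_seed_gives_identical_dataset(self):
        cfg = StudyConfig(n_per_group=2, sigma_mm=0.3, motions=("abduction",))
        a = gk.generate_study(cfg, seed=5)
        b = gk.generate_study(cfg, seed=5)
        assert a.metadata.equals(b.metadata)
        assert a.realized_offsets.equals(b.realized_offsets)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.trajectories.positions, tb.trajectories.positions)

    def test_different_seed_differs(self):
        cfg = StudyConfig(n_per_group=2, sigma_mm=0.3, motions=("abduction",))
        a = gk.generate_study(cfg, seed=5)
        c = gk.generate_study(cfg, seed=6)
        assert not np.array_equal(
            a.trials[0].trajectories.positions, c.trials[0].trajectories.positions
        )

    def test_design_shape(self):
        cfg = StudyConfig(n_per_group=2, motions=("abduction", "flexion"))
        ds = gk.generate_study(cfg, seed=1)
        assert len(ds.trials) == 2 * 2 * 7 * 2  # groups x shoulders x conditions x motions
        assert set(ds.metadata["group"]) == {"AC_first", "CC_first"}
        left = ds.metadata[ds.metadata["side"] == "left"]
        assert set(left["group"]) == {"AC_first"}

    def test_too_few_shoulders_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            StudyConfig(n_per_group=1)

    def test_logistic_dispersion_matches_target_iqr(self, rng):
        spec = ScenarioSpec(offset_median=(0.0,) * 6, offset_iqr=(4.0,) * 6)
        draws = sample_alignment_offsets(spec, 40000, rng)
        q1, q3 = np.percentile(draws[:, 2], [25, 75])
        assert q3 - q1 == pytest.approx(4.0, rel=0.05)

    def test_study_roundtrips_through_disk(self, tmp_path):
        from girdlekin.mocap_io import read_marker_tsv
        from girdlekin.synth import write_study

        cfg = StudyConfig(n_per_group=2, motions=("abduction",), sigma_mm=0.1)
        ds = gk.generate_study(cfg, seed=2)
        write_study(ds, tmp_path, fmt="tsv")
        assert (tmp_path / "metadata.csv").exists()
        assert (tmp_path / "config.json").exists()
        m = ds.trials[0].metadata
        back = read_marker_tsv(tmp_path / f"{m.shoulder}_{m.condition}_{m.motion_type}.tsv")
        assert np.abs(back.positions - ds.trials[0].trajectories.positions).max() < 1e-8


class TestStatisticalCalibration:
    def test_zero_effect_study_type_i_error(self):
        """Pooled Mann-Whitney on a null-effect study rejects at ~alpha."""
        from girdlekin.stats import mann_whitney

        rng = np.random.default_rng(101)
        spec = ScenarioSpec(offset_median=(0.0,) * 6, offset_iqr=(4.0,) * 6)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            # 5 shoulders x 4 construct conditions pooled per group
            a = sample_alignment_offsets(spec, 20, rng)[:, 2]
            b = sample_alignment_offsets(spec, 20, rng)[:, 2]
            rejections += mann_whitney(a, b).p_value <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_tilt_effect_detected_with_study_power(self):
        """The emulated tilt effect is detected in well over half of replicates."""
        from girdlekin.stats import mann_whitney

        rng = np.random.default_rng(202)
        ac = ScenarioSpec(offset_median=(-1.9, 0.2, -10.1, -2.2, 0.8, 1.0),
                          offset_iqr=(2.0, 3.0, 3.0, 2.0, 2.5, 1.6))
        cc = ScenarioSpec(offset_median=(-1.1, 2.1, -0.7, -3.7, 2.4, 2.3),
                          offset_iqr=(3.8, 2.1, 7.8, 3.5, 2.2, 5.0))
        detected = sum(
            mann_whitney(
                sample_alignment_offsets(ac, 5, rng)[:, 2],
                sample_alignment_offsets(cc, 5, rng)[:, 2],
            ).p_value
            <= 0.05
            for _ in range(400)
        )
        assert detected / 400 >= 0.5
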