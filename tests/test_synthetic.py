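"""Synthetic cohort generator: determinism, label balance, amplitude calibration."""

import json

import numpy as np
import pytest

from scrubseq.core import ROUTINE_ORDER, read_session
from scrubseq.synthetic import (
    SimConfig,
    _rotate_channels,
    default_templates,
    draw_subject_profiles,
    simulate_cohort,
    simulate_session,
    template_pairwise_cosine_distances,
)


class TestTemplates:
    def test_deterministic_and_complete(self):
        a = default_templates(1.0, seed=7)
        b = default_templates(1.0, seed=7)
        assert [t.label for t in a] == list(ROUTINE_ORDER)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.emg_activation, tb.emg_activation)
            assert ta.motion_freq == tb.motion_freq

    def test_separation_scales_pairwise_distance(self):
        d_hi = template_pairwise_cosine_distances(default_templates(1.0, seed=3)).min()
        d_lo = template_pairwise_cosine_distances(default_templates(0.1, seed=3)).min()
        assert d_hi > d_lo
        assert d_hi >= 0.1  # enforced minimum at separation 1.0

    def test_separation_out_of_range(self):
        with pytest.raises(ValueError):
            default_templates(0.0, seed=1)
        with pytest.raises(ValueError):
            default_templates(1.5, seed=1)


class TestSimulateSession:
    def test_shapes_default_config(self, synthetic_session):
        # 9 gestures x 5 s at 200/50 Hz
        assert synthetic_session.left.emg.shape == (9000, 8)
        assert synthetic_session.left.imu.shape == (2250, 10)
        assert synthetic_session.n_frames == 2250

    def test_label_balance(self, synthetic_session):
        ords = synthetic_session.label_ordinals()
        counts = np.bincount(ords, minlength=9)
        assert np.all(counts == 250)
        # routine order: labels are sorted by ordinal
        assert np.all(np.diff(ords) >= 0)

    def test_determinism(self, templates, sim_config):
        prof = draw_subject_profiles(sim_config)[0]
        s1 = simulate_session(templates, prof, sim_config, repetition=1, seed=13)
        s2 = simulate_session(templates, prof, sim_config, repetition=1, seed=13)
        np.testing.assert_array_equal(s1.left.emg, s2.left.emg)
        np.testing.assert_array_equal(s1.right.emg, s2.right.emg)
        np.testing.assert_array_equal(s1.left.imu, s2.left.imu)

    def test_zero_activation_zero_noise_gives_silence(self, templates, sim_config):
        import dataclasses

        silent = [
            dataclasses.replace(t, emg_activation=np.zeros((2, 8))) for t in templates
        ]
        prof = draw_subject_profiles(sim_config)[0]
        prof = dataclasses.replace(prof, noise_floor=0.0)
        s = simulate_session(silent, prof, sim_config, repetition=1, seed=1)
        assert np.all(s.left.emg == 0) and np.all(s.right.emg == 0)

    def test_emg_rms_matches_gain_times_template(self, templates, sim_config):
        prof = draw_subject_profiles(sim_config)[0]
        s = simulate_session(templates, prof, sim_config, repetition=1, seed=2)
        angle = prof.placement_angles[0]
        for gi in [0, 4, 8]:
            seg = s.left.emg[gi * 1000 : (gi + 1) * 1000].astype(float)
            expected = prof.channel_gain[0] * _rotate_channels(
                templates[gi].emg_activation[0], angle
            )
            rms = np.sqrt((seg**2).mean(axis=0))
            # noise floor adds (quadratically) on top of the gesture signal
            expected = np.sqrt(expected**2 + prof.noise_floor**2)
            np.testing.assert_allclose(rms, expected, rtol=0.10)

    def test_clipping_rate_below_one_percent(self, synthetic_session):
        for arm in (synthetic_session.left, synthetic_session.right):
            clip = np.mean((arm.emg == 127) | (arm.emg == -128))
            assert clip < 0.01

    def test_quaternions_unit_norm(self, synthetic_session):
        q = synthetic_session.left.imu[:, :4]
        np.testing.assert_allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-9)

    def test_repetition_out_of_range(self, templates, sim_config):
        prof = draw_subject_profiles(sim_config)[0]
        with pytest.raises(ValueError, match="repetition"):
            simulate_session(templates, prof, sim_config, repetition=5)


class TestChannelRotation:
    def test_zero_angle_is_identity(self):
        rms = np.arange(8.0)
        np.testing.assert_array_equal(_rotate_channels(rms, 0.0), rms)

    def test_full_channel_spacing_is_roll(self):
        rms = np.arange(8.0)
        np.testing.assert_allclose(_rotate_channels(rms, 2 * np.pi / 8), np.roll(rms, 1))

    def test_half_channel_mixes_neighbours(self):
        rms = np.zeros(8)
        rms[0] = 1.0
        mixed = _rotate_channels(rms, np.pi / 8)  # half the 45-degree spacing
        assert mixed[0] == pytest.approx(0.5) and mixed[1] == pytest.approx(0.5)


class TestCohort:
    def test_cohort_layout_and_determinism(self, tmp_path):
        cfg = SimConfig(n_subjects=2, n_repetitions=2, seed=9)
        man1 = simulate_cohort(cfg, tmp_path / "a")
        man2 = simulate_cohort(cfg, tmp_path / "b")
        assert len(man1.sessions) == 4
        assert man1.sessions == man2.sessions
        assert man1.subjects == ["S01", "S02"]
        # identical file contents across runs
        for rel in man1.sessions:
            s1 = read_session(tmp_path / "a" / rel)
            s2 = read_session(tmp_path / "b" / rel)
            np.testing.assert_array_equal(s1.left.emg, s2.left.emg)
        # manifest is valid JSON listing the session dirs
        doc = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert doc["sessions"] == man1.sessions

    def test_single_session_cohort(self, tmp_path):
        cfg = SimConfig(n_subjects=1, n_repetitions=1, seed=1)
        man = simulate_cohort(cfg, tmp_path / "c")
        assert len(man.sessions) == 1
        read_session(man.session_paths()[0])  # round-trips as a valid session


class TestSeparabilityControl:
    def test_accuracy_monotone_in_separation(self, tmp_path):
        """Held-out frame accuracy is non-decreasing in the separation dial
        over {0.2, 0.5, 1.0}, averaged over 3 seeds.

        Scaled down for runtime (4 subjects x 1 rep, 3 s gestures, level-1
        features, small networks): the ordering of the means is the claim,
        not the absolute rates.
        """
        from scrubseq.ann import TrainConfig
        from scrubseq.evaluation import run_cv
        from scrubseq.features import FeatureConfig

        feat = FeatureConfig(wavelet_level=1)
        train = TrainConfig(hidden_nodes=8, max_iter=50, seed=0)
        means = []
        for sep in (0.2, 0.5, 1.0):
            rates = []
            for seed in (1, 2, 3):
                cfg = SimConfig(
                    n_subjects=4, n_repetitions=1, gesture_duration_s=3.0,
                    seed=seed, separation=sep,
                )
                man = simulate_cohort(cfg, tmp_path / f"sep{sep}_{seed}")
                rep = run_cv(man, feat, train, k=2, seed=seed)
                rates.append(rep.mean_rate_ann)
            means.append(np.mean(rates))
        assert means[0] <= means[1] <= means[2]
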