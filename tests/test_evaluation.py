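"""Cross-validation harness: fold arithmetic, conservation, oracle predictor."""

import numpy as np
import pytest

from scrubseq.ann import TrainConfig
from scrubseq.evaluation import EvalReport, confusion_matrix, run_cv, subject_kfold, sweep
from scrubseq.features import FeatureConfig
from scrubseq.hmm import build_who_chain

FAST_TRAIN = TrainConfig(hidden_nodes=8, max_iter=60, seed=2)
FAST_FEAT = FeatureConfig(wavelet_level=1)


class TestSubjectKfold:
    def test_17_subjects_5_folds(self):
        subjects = [f"S{i:02d}" for i in range(1, 18)]
        split = subject_kfold(subjects, 5, seed=0)
        sizes = sorted(len(f) for f in split.folds)
        assert sizes == [3, 3, 3, 4, 4]
        assert set().union(*split.folds) == set(subjects)

    def test_leave_one_subject_out(self):
        subjects = ["a", "b", "c"]
        split = subject_kfold(subjects, 3, seed=1)
        assert sorted(len(f) for f in split.folds) == [1, 1, 1]

    def test_deterministic_and_seed_sensitive(self):
        subjects = [f"S{i}" for i in range(10)]
        assert subject_kfold(subjects, 4, seed=5).folds == subject_kfold(subjects, 4, seed=5).folds
        assert subject_kfold(subjects, 4, seed=5).folds != subject_kfold(subjects, 4, seed=6).folds

    def test_k_larger_than_roster_rejected(self):
        with pytest.raises(ValueError, match="k="):
            subject_kfold(["a", "b"], 3)


class TestRunCV:
    def test_oracle_predictor_gives_perfect_rates(self, small_cohort_dir):
        _, manifest = small_cohort_dir
        report = run_cv(
            manifest,
            FAST_FEAT,
            FAST_TRAIN,
            build_who_chain(),
            k=2,
            seed=0,
            predictor=lambda train, test: test.label_ordinals(),
        )
        assert report.mean_rate_ann == 1.0
        assert report.mean_rate_hmm == 1.0
        for f in report.per_fold:
            cm = f.confusion_ann
            assert np.all(cm == np.diag(np.diag(cm)))

    def test_confusion_conservation_and_reproducibility(self, small_cohort_dir):
        _, manifest = small_cohort_dir
        kw = dict(k=2, seed=3)
        r1 = run_cv(manifest, FAST_FEAT, FAST_TRAIN, build_who_chain(), **kw)
        r2 = run_cv(manifest, FAST_FEAT, FAST_TRAIN, build_who_chain(), **kw)
        total = 0
        for f1, f2 in zip(r1.per_fold, r2.per_fold):
            # same test frames before and after smoothing
            np.testing.assert_array_equal(
                f1.confusion_ann.sum(axis=1), f1.confusion_hmm.sum(axis=1)
            )
            # row sums = per-gesture frame counts (250 per session)
            assert f1.confusion_ann.sum() % 2250 == 0
            np.testing.assert_array_equal(f1.confusion_ann, f2.confusion_ann)
            assert f1.rate_hmm == f2.rate_hmm
            total += f1.confusion_ann.sum()
        assert total == 4 * 2250  # every frame of every session tested once

    def test_trained_pipeline_learns_and_hmm_helps(self, small_cohort_dir):
        _, manifest = small_cohort_dir
        report = run_cv(manifest, FAST_FEAT, FAST_TRAIN, build_who_chain(), k=2, seed=0)
        assert report.mean_rate_ann > 0.8  # far above the 1/9 chance level
        assert report.mean_rate_hmm >= report.mean_rate_ann
        for f in report.per_fold:
            assert f.rate_hmm >= f.rate_ann


class TestSweep:
    def test_wavelet_level_reports_feature_dims(self, small_cohort_dir):
        _, manifest = small_cohort_dir
        table = sweep(
            manifest, "wavelet_level", [0, 3], FAST_FEAT, FAST_TRAIN, k=2, seed=0
        )
        assert list(table["feature_dim"]) == [72, 180]
        assert table["mean_rate_ann"].between(0, 1).all()

    def test_single_value_matches_direct_run(self, small_cohort_dir):
        _, manifest = small_cohort_dir
        table = sweep(manifest, "nodes", [8], FAST_FEAT, FAST_TRAIN, k=2, seed=0)
        direct = run_cv(manifest, FAST_FEAT, FAST_TRAIN, build_who_chain(), k=2, seed=0)
        assert table.loc[0, "mean_rate_ann"] == pytest.approx(direct.mean_rate_ann)
        assert table.loc[0, "mean_rate_hmm"] == pytest.approx(direct.mean_rate_hmm)

    def test_unknown_axis_rejected(self, small_cohort_dir):
        _, manifest = small_cohort_dir
        with pytest.raises(ValueError, match="axis"):
            sweep(manifest, "dropout", [0.1], FAST_FEAT, FAST_TRAIN)


def test_confusion_matrix_counts():
    true = np.array([0, 0, 1, 2, 2, 2])
    pred = np.array([0, 1, 1, 2, 2, 0])
    cm = confusion_matrix(true, pred)
    assert cm[0, 0] == 1 and cm[0, 1] == 1 and cm[2, 2] == 2 and cm[2, 0] == 1
    assert cm.sum() == 6


def test_report_std_is_sample_std():
    from scrubseq.evaluation import FoldResult

    folds = [
        FoldResult(i, [], np.eye(9, dtype=int), np.eye(9, dtype=int), r, r)
        for i, r in enumerate([0.9, 0.95, 1.0])
    ]
    rep = EvalReport.from_folds(folds)
    assert rep.mean_rate_ann == pytest.approx(0.95)
    assert rep.std_rate_ann == pytest.approx(np.std([0.9, 0.95, 1.0], ddof=1))


def test_plot_outputs_written(tmp_path, small_cohort_dir):
    import pandas as pd

    from scrubseq.evaluation import plot_smoothing, plot_sweep

    table = pd.DataFrame(
        {
            "axis": ["nodes", "nodes"],
            "value": [5, 25],
            "feature_dim": [72, 72],
            "mean_rate_ann": [0.9, 0.95],
            "std_rate_ann": [0.01, 0.01],
            "mean_rate_hmm": [0.95, 0.97],
            "std_rate_hmm": [0.01, 0.01],
        }
    )
    p1 = plot_sweep(table, tmp_path / "sweep.png")
    truth = np.repeat(np.arange(9), 50)
    noisy = truth.copy()
    noisy[::17] = (noisy[::17] + 3) % 9
    p2 = plot_smoothing(truth, noisy, truth, tmp_path / "smooth.png")
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0
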