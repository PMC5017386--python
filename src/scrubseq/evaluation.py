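"""Subject-wise cross-validation, confusion matrices, and parameter sweeps.

Generalization to unseen wearers is the quantity of interest, so folds are
formed over *subjects*: every session of a subject lands in the same fold,
and the feature standardizer and networks are fitted on training-fold
subjects only.  The recognition rate is frame-level accuracy over all test
frames, reported before (raw classifier) and after chain-HMM smoothing; the
smoother is applied per session, since each session is one routine instance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ann import TrainConfig, predict_frames, train_ensemble
from .core import (
    DatasetManifest,
    GestureLabel,
    N_GESTURES,
    read_session,
)
from .features import FeatureConfig, FeatureMatrix, extract_features, feature_dimension
from .hmm import ChainHMM, build_who_chain, smooth_predictions

__all__ = [
    "FoldSplit",
    "FoldResult",
    "EvalReport",
    "subject_kfold",
    "run_cv",
    "sweep",
    "confusion_matrix",
]


@dataclass(frozen=True)
class FoldSplit:
    """Disjoint subject sets covering the whole roster."""

    folds: list[frozenset]
    seed: int

    def __post_init__(self):
        all_subjects = [s for f in self.folds for s in f]
        if len(all_subjects) != len(set(all_subjects)):
            raise ValueError("folds must be disjoint")


@dataclass
class FoldResult:
    fold: int
    test_subjects: list[str]
    confusion_ann: np.ndarray  # 9x9 counts, rows = true label
    confusion_hmm: np.ndarray
    rate_ann: float
    rate_hmm: float


@dataclass
class EvalReport:
    """Per-fold confusion matrices and recognition rates, with across-fold
    mean and sample (n-1) standard deviation."""

    per_fold: list[FoldResult]
    mean_rate_ann: float
    std_rate_ann: float
    mean_rate_hmm: float
    std_rate_hmm: float

    @classmethod
    def from_folds(cls, folds: list[FoldResult]) -> "EvalReport":
        ra = np.array([f.rate_ann for f in folds])
        rh = np.array([f.rate_hmm for f in folds])
        ddof = 1 if len(folds) > 1 else 0
        return cls(
            per_fold=folds,
            mean_rate_ann=float(ra.mean()),
            std_rate_ann=float(ra.std(ddof=ddof)),
            mean_rate_hmm=float(rh.mean()),
            std_rate_hmm=float(rh.std(ddof=ddof)),
        )

    def total_confusions(self) -> tuple[np.ndarray, np.ndarray]:
        ann = sum(f.confusion_ann for f in self.per_fold)
        hmm = sum(f.confusion_hmm for f in self.per_fold)
        return ann, hmm

    def to_dict(self) -> dict:
        return {
            "mean_rate_ann": self.mean_rate_ann,
            "std_rate_ann": self.std_rate_ann,
            "mean_rate_hmm": self.mean_rate_hmm,
            "std_rate_hmm": self.std_rate_hmm,
            "per_fold": [
                {
                    "fold": f.fold,
                    "test_subjects": list(f.test_subjects),
                    "rate_ann": f.rate_ann,
                    "rate_hmm": f.rate_hmm,
                    "confusion_ann": f.confusion_ann.tolist(),
                    "confusion_hmm": f.confusion_hmm.tolist(),
                }
                for f in self.per_fold
            ],
        }


def subject_kfold(subjects: list[str], k: int, seed: int = 0) -> FoldSplit:
    """Seeded shuffle of the roster, then a contiguous split into k folds
    whose sizes differ by at most one (17 subjects, k=5 -> 4+4+3+3+3)."""
    if k < 1 or k > len(subjects):
        raise ValueError(f"k={k} must be between 1 and the number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    folds = [frozenset(part) for part in np.array_split(np.array(shuffled, dtype=object), k)]
    return FoldSplit(folds=folds, seed=seed)


def confusion_matrix(true_ord: np.ndarray, pred_ord: np.ndarray) -> np.ndarray:
    """9x9 count matrix, rows = true gesture ordinal, columns = predicted."""
    cm = np.zeros((N_GESTURES, N_GESTURES), dtype=np.int64)
    np.add.at(cm, (true_ord, pred_ord), 1)
    return cm


def _load_features(
    manifest: DatasetManifest, feat_cfg: FeatureConfig
) -> list[tuple[str, FeatureMatrix]]:
    """(subject_id, feature matrix) per session, in manifest order."""
    out = []
    for path in manifest.session_paths():
        sess = read_session(path)
        out.append((sess.subject_id, extract_features(sess, feat_cfg)))
    return out


def run_cv(
    manifest: DatasetManifest,
    feat_cfg: FeatureConfig | None = None,
    train_cfg: TrainConfig | None = None,
    hmm: ChainHMM | None = None,
    k: int = 5,
    seed: int = 0,
    predictor=None,
) -> EvalReport:
    """Subject-wise k-fold cross-validation of the full pipeline.

    For each fold: features of the training subjects are stacked, the
    standardizer and one-vs-all ensemble are fitted on them alone, every test
    session is predicted frame-by-frame, and its label sequence is decoded
    with the chain HMM.  ``predictor`` is a test hook replacing the trained
    ensemble: a callable ``(train_features, test_features) -> ordinals``.
    """
    feat_cfg = feat_cfg or FeatureConfig()
    train_cfg = train_cfg or TrainConfig()
    hmm = hmm or build_who_chain()

    per_session = _load_features(manifest, feat_cfg)
    split = subject_kfold(list(manifest.subjects), k, seed)

    results = []
    for fold_idx, test_subjects in enumerate(split.folds):
        train_mats = [fm for sid, fm in per_session if sid not in test_subjects]
        test_sessions = [fm for sid, fm in per_session if sid in test_subjects]
        if not train_mats or not test_sessions:
            raise ValueError(f"fold {fold_idx}: empty train or test partition")

        train_all = FeatureMatrix(
            X=np.vstack([fm.X for fm in train_mats]),
            frame_labels=[g for fm in train_mats for g in fm.frame_labels],
            column_layout=train_mats[0].column_layout,
            config=feat_cfg,
        )
        if predictor is None:
            try:
                ensemble = train_ensemble(train_all, train_cfg)
            except Exception as e:
                raise RuntimeError(f"fold {fold_idx}: training failed: {e}") from e

        cm_ann = np.zeros((N_GESTURES, N_GESTURES), dtype=np.int64)
        cm_hmm = np.zeros((N_GESTURES, N_GESTURES), dtype=np.int64)
        for fm in test_sessions:
            true = fm.label_ordinals()
            if predictor is None:
                pred_labels, _ = predict_frames(ensemble, fm)
                pred = np.asarray([g.ordinal for g in pred_labels])
            else:
                pred = np.asarray(predictor(train_all, fm))
            smoothed = smooth_predictions(
                [GestureLabel.from_ordinal(i) for i in pred], hmm
            )
            pred_hmm = np.asarray([g.ordinal for g in smoothed])
            cm_ann += confusion_matrix(true, pred)
            cm_hmm += confusion_matrix(true, pred_hmm)

        n = cm_ann.sum()
        results.append(
            FoldResult(
                fold=fold_idx,
                test_subjects=sorted(test_subjects),
                confusion_ann=cm_ann,
                confusion_hmm=cm_hmm,
                rate_ann=float(np.trace(cm_ann) / n),
                rate_hmm=float(np.trace(cm_hmm) / n),
            )
        )
    return EvalReport.from_folds(results)


SWEEP_AXES = ("nodes", "layers", "wavelet_level")


def sweep(
    manifest: DatasetManifest,
    axis: str,
    values: list,
    feat_cfg: FeatureConfig | None = None,
    train_cfg: TrainConfig | None = None,
    hmm: ChainHMM | None = None,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run the cross-validation varying one hyperparameter axis.

    Mirrors the incremental optimization protocol: ``nodes`` (hidden nodes
    per layer), ``layers`` (hidden layer count) or ``wavelet_level``.
    Returns a tidy table (value, feature_dim, mean/std rates per stage).
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")
    if not values:
        raise ValueError("values must be non-empty")
    feat_cfg = feat_cfg or FeatureConfig()
    train_cfg = train_cfg or TrainConfig()

    rows = []
    for v in values:
        fc, tc = feat_cfg, train_cfg
        if axis == "nodes":
            tc = replace(train_cfg, hidden_nodes=int(v))
        elif axis == "layers":
            tc = replace(train_cfg, hidden_layers=int(v))
        else:
            fc = replace(feat_cfg, wavelet_level=int(v))
        report = run_cv(manifest, fc, tc, hmm, k=k, seed=seed)
        rows.append(
            {
                "axis": axis,
                "value": v,
                "feature_dim": feature_dimension(fc.wavelet_level),
                "mean_rate_ann": report.mean_rate_ann,
                "std_rate_ann": report.std_rate_ann,
                "mean_rate_hmm": report.mean_rate_hmm,
                "std_rate_hmm": report.std_rate_hmm,
            }
        )
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, out_path: Path) -> Path:
    """Recognition-rate curves (classifier vs HMM-smoothed) along the swept
    axis, in the style of an incremental tuning figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(table["value"], 100 * table["mean_rate_ann"], "o-", label="ANN")
    ax.plot(table["value"], 100 * table["mean_rate_hmm"], "s--", label="ANN + HMM")
    ax.set_xlabel(str(table["axis"].iloc[0]))
    ax.set_ylabel("recognition rate (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_smoothing(
    true_ord: np.ndarray, ann_ord: np.ndarray, hmm_ord: np.ndarray, out_path: Path
) -> Path:
    """Illustrate the effect of HMM smoothing on one session's label track."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(len(true_ord)) / 50.0
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.step(t, ann_ord, where="post", lw=0.8, alpha=0.6, label="classifier")
    ax.step(t, hmm_ord, where="post", lw=1.6, label="HMM-smoothed")
    ax.step(t, true_ord, where="post", lw=0.8, ls=":", color="k", label="truth")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("gesture ordinal")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
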