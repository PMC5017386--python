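"""Per-frame feature extraction with cross-rate alignment.

EMG (200 Hz) and IMU (50 Hz) run at different rates; classification works at
the IMU frame rate.  Rather than downsampling the raw EMG (which would
discard its high-frequency content), features are computed per channel at
full EMG resolution and the *feature vectors* are decimated: for IMU frame i
the EMG window is centered on EMG sample 4*i.  Each frame contributes

* 16 raw EMG values (the center sample of each of 2 arms x 8 channels),
* 16 x (L+1) EMG wavelet log-energies,
* 20 raw IMU values (current sample of 2 arms x 10 channels),
* 20 x (L+1) IMU wavelet log-energies,

for a total of D = 36 + 36*(L+1) features; L = 10 gives the reference
16 + 16*11 + 20 + 20*11 = 432.  Wavelet blocks are channel-major: for each
channel, the L detail log-energies (fine to coarse) then the approximation.
Windows are centered and reflection-padded at the session edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    EMG_PER_IMU,
    GestureLabel,
    SessionRecording,
)
from .wavelets import wavelet_level_features

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "extract_features",
    "feature_dimension",
    "save_feature_store",
    "load_feature_store",
]

N_EMG_TOTAL = 16  # 2 arms x 8 channels
N_IMU_TOTAL = 20  # 2 arms x 10 channels


@dataclass(frozen=True)
class FeatureConfig:
    """Wavelet depth L, Daubechies order, and analysis window lengths.

    ``emg_window`` (samples at 200 Hz) and ``imu_window`` (samples at 50 Hz)
    default to 128 and 32: both span 0.64 s, so the two modalities see the
    same time horizon.  ``energy_epsilon`` floors band energies before the
    log so silent bands map to log10(eps) instead of -inf.
    """

    wavelet_level: int = 10
    wavelet_order: int = 4
    emg_window: int = 128
    imu_window: int = 32
    energy_epsilon: float = 1e-12

    def __post_init__(self):
        if self.wavelet_level < 0:
            raise ValueError("wavelet_level must be >= 0")
        if self.emg_window < 2 or self.imu_window < 2:
            raise ValueError("windows must contain at least 2 samples")
        if self.wavelet_order < 1:
            raise ValueError("wavelet_order must be >= 1")
        if self.energy_epsilon <= 0:
            raise ValueError("energy_epsilon must be positive")


@dataclass
class FeatureMatrix:
    """Frame-rate feature matrix [n_frames x D] with its label track and the
    ordered column layout (block name -> column slice)."""

    X: np.ndarray
    frame_labels: list[GestureLabel]
    column_layout: dict[str, slice]
    config: FeatureConfig

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def label_ordinals(self) -> np.ndarray:
        return np.asarray([g.ordinal for g in self.frame_labels], dtype=np.int64)


def feature_dimension(level: int) -> int:
    """D = 36 + 36*(L+1): raw EMG+IMU values plus one (L+1)-band wavelet
    block per channel."""
    return (N_EMG_TOTAL + N_IMU_TOTAL) * (level + 2)


def _centered_windows(x: np.ndarray, centers: np.ndarray, width: int) -> np.ndarray:
    """Windows of ``width`` centered on ``centers`` (center at width//2),
    reflection-padded at the edges.  x: (n, c) -> (len(centers), c, width)."""
    n = x.shape[0]
    left = width // 2
    right = width - left - 1
    if n < 2:
        raise ValueError("signal too short for windowing")
    pad = np.pad(x, ((left, right), (0, 0)), mode="reflect")
    idx = centers[:, None] + np.arange(width)[None, :]  # already offset by +left
    return pad[idx].transpose(0, 2, 1)


def extract_features(session: SessionRecording, cfg: FeatureConfig) -> FeatureMatrix:
    """Extract the per-frame feature matrix of a session.

    For each IMU frame i: a centered ``emg_window`` around EMG sample 4*i per
    EMG channel (both arms) and a centered ``imu_window`` around IMU sample i
    per IMU channel.  Raw features are the center samples; wavelet features
    are per-level log-energies.  Frame labels pass through unchanged.
    """
    n_frames = session.n_frames
    n_emg = session.left.n_emg
    min_frames = max(cfg.imu_window, -(-cfg.emg_window // EMG_PER_IMU))
    if n_frames < min_frames:
        raise ValueError(
            f"session has {n_frames} frames; feature extraction needs at least "
            f"{min_frames} frames ({min_frames / 50:.2f} s) for the configured windows"
        )

    emg = np.hstack([session.left.emg, session.right.emg]).astype(float)  # (n_emg, 16)
    imu = np.hstack([session.left.imu, session.right.imu])  # (n_frames, 20)

    emg_centers = np.minimum(np.arange(n_frames) * EMG_PER_IMU, n_emg - 1)
    emg_win = _centered_windows(emg, emg_centers, cfg.emg_window)  # (F, 16, W)
    imu_win = _centered_windows(imu, np.arange(n_frames), cfg.imu_window)  # (F, 20, w)

    L, order, eps = cfg.wavelet_level, cfg.wavelet_order, cfg.energy_epsilon
    emg_wav = wavelet_level_features(emg_win, L, order, eps).reshape(n_frames, -1)
    imu_wav = wavelet_level_features(imu_win, L, order, eps).reshape(n_frames, -1)

    raw_emg = emg[emg_centers]  # (F, 16)
    raw_imu = imu  # (F, 20)

    X = np.hstack([raw_emg, emg_wav, raw_imu, imu_wav])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values produced")
    assert X.shape[1] == feature_dimension(L)

    b = L + 1
    layout = {
        "emg_raw": slice(0, 16),
        "emg_wavelet": slice(16, 16 + 16 * b),
        "imu_raw": slice(16 + 16 * b, 36 + 16 * b),
        "imu_wavelet": slice(36 + 16 * b, 36 + 36 * b),
    }
    return FeatureMatrix(
        X=X, frame_labels=list(session.labels), column_layout=layout, config=cfg
    )


# ---------------------------------------------------------------------------
# HDF5 feature store: one group per session, config in root attributes


def save_feature_store(
    entries: "list[tuple[str, int, FeatureMatrix]]", path
) -> None:
    """Persist (subject_id, repetition, FeatureMatrix) triples to HDF5.

    Root attributes carry the FeatureConfig; each session becomes a group
    ``s000, s001, ...`` holding ``X`` and integer ``labels`` (gesture
    ordinals) with subject/repetition attributes.
    """
    import h5py

    if not entries:
        raise ValueError("nothing to save")
    cfg = entries[0][2].config
    with h5py.File(path, "w") as f:
        for k, v in (
            ("wavelet_level", cfg.wavelet_level),
            ("wavelet_order", cfg.wavelet_order),
            ("emg_window", cfg.emg_window),
            ("imu_window", cfg.imu_window),
            ("energy_epsilon", cfg.energy_epsilon),
        ):
            f.attrs[k] = v
        for i, (subject_id, repetition, fm) in enumerate(entries):
            grp = f.create_group(f"s{i:03d}")
            grp.create_dataset("X", data=fm.X)
            grp.create_dataset("labels", data=fm.label_ordinals())
            grp.attrs["subject_id"] = subject_id
            grp.attrs["repetition"] = int(repetition)


def load_feature_store(path) -> "list[tuple[str, int, FeatureMatrix]]":
    """Inverse of :func:`save_feature_store`."""
    import h5py

    from .core import GestureLabel

    entries = []
    with h5py.File(path, "r") as f:
        cfg = FeatureConfig(
            wavelet_level=int(f.attrs["wavelet_level"]),
            wavelet_order=int(f.attrs["wavelet_order"]),
            emg_window=int(f.attrs["emg_window"]),
            imu_window=int(f.attrs["imu_window"]),
            energy_epsilon=float(f.attrs["energy_epsilon"]),
        )
        b = cfg.wavelet_level + 1
        layout = {
            "emg_raw": slice(0, 16),
            "emg_wavelet": slice(16, 16 + 16 * b),
            "imu_raw": slice(16 + 16 * b, 36 + 16 * b),
            "imu_wavelet": slice(36 + 16 * b, 36 + 36 * b),
        }
        for name in sorted(f.keys()):
            grp = f[name]
            labels = [GestureLabel.from_ordinal(i) for i in grp["labels"][()]]
            fm = FeatureMatrix(
                X=grp["X"][()], frame_labels=labels, column_layout=layout, config=cfg
            )
            entries.append((str(grp.attrs["subject_id"]), int(grp.attrs["repetition"]), fm))
    return entries
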