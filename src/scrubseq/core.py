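"""Domain types and on-disk format for dual-armband hand-hygiene recordings.

A recording session captures one performance of the WHO hand-rub routine by
one subject wearing one gesture-control armband per forearm.  Each armband
delivers an 8-channel surface-EMG stream (int8 samples at 200 Hz) and a
10-channel IMU stream (orientation quaternion, linear acceleration, angular
velocity; float samples at 50 Hz).  Gesture labels are defined per IMU frame,
i.e. at 50 Hz, because classification is frame-aligned to the IMU rate.

Sessions are stored as a directory of plain CSV files plus a ``meta.json``,
so recordings stay human-inspectable and diff-able.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

EMG_RATE_HZ = 200
IMU_RATE_HZ = 50
EMG_PER_IMU = EMG_RATE_HZ // IMU_RATE_HZ  # 4 EMG samples per label frame
N_EMG_CHANNELS = 8
N_IMU_CHANNELS = 10

SCHEMA_VERSION = "1.0"

IMU_COLUMNS = ("qw", "qx", "qy", "qz", "ax", "ay", "az", "gx", "gy", "gz")
EMG_COLUMNS = tuple(f"ch{i}" for i in range(1, N_EMG_CHANNELS + 1))


class GestureLabel(Enum):
    """The nine WHO hand-hygiene gestures in routine order.

    Six basic movements, with the asymmetric ones duplicated for leading
    left/right hand: palm-to-palm (G1), back of hands (G2L/G2R), palms with
    interlaced fingers (G3), backs of fingers (G4), thumbs (G5L/G5R),
    fingertips and nails (G6L/G6R).  ``ordinal`` is the position in the
    prescribed routine, 0-8.
    """

    G1 = 0
    G2L = 1
    G2R = 2
    G3 = 3
    G4 = 4
    G5L = 5
    G5R = 6
    G6L = 7
    G6R = 8

    @property
    def ordinal(self) -> int:
        return self.value

    @classmethod
    def from_ordinal(cls, i: int) -> "GestureLabel":
        return _BY_ORDINAL[int(i)]

    @classmethod
    def from_code(cls, code: str) -> "GestureLabel":
        try:
            return cls[code]
        except KeyError:
            raise ValueError(
                f"unknown gesture label {code!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


_BY_ORDINAL = {m.value: m for m in GestureLabel}

ROUTINE_ORDER = tuple(GestureLabel.from_ordinal(i) for i in range(9))
N_GESTURES = len(ROUTINE_ORDER)


class ValidationError(ValueError):
    """A recording violates the stream/session contract."""


def labels_to_ordinals(labels) -> np.ndarray:
    """Vector of GestureLabel -> int ordinal array."""
    return np.asarray([g.ordinal for g in labels], dtype=np.int64)


def ordinals_to_labels(ordinals) -> list[GestureLabel]:
    return [GestureLabel.from_ordinal(i) for i in np.asarray(ordinals)]


@dataclass
class ArmbandStream:
    """Raw streams of one armband: EMG [n_emg x 8] int8-range at 200 Hz and
    IMU [n_imu x 10] float at 50 Hz (qw,qx,qy,qz, ax,ay,az, gx,gy,gz),
    sharing the start time ``t0`` (seconds)."""

    emg: np.ndarray
    imu: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.emg = np.asarray(self.emg)
        self.imu = np.asarray(self.imu, dtype=float)
        self.validate()

    @property
    def n_emg(self) -> int:
        return self.emg.shape[0]

    @property
    def n_imu(self) -> int:
        return self.imu.shape[0]

    def validate(self) -> None:
        if self.emg.ndim != 2 or self.emg.shape[1] != N_EMG_CHANNELS:
            raise ValidationError(f"EMG must be [n x {N_EMG_CHANNELS}], got {self.emg.shape}")
        if self.imu.ndim != 2 or self.imu.shape[1] != N_IMU_CHANNELS:
            raise ValidationError(f"IMU must be [n x {N_IMU_CHANNELS}], got {self.imu.shape}")
        if self.emg.size and (self.emg.min() < -128 or self.emg.max() > 127):
            bad = np.argwhere((self.emg < -128) | (self.emg > 127))[0]
            raise ValidationError(
                f"EMG sample outside int8 range at row {bad[0]} column {bad[1]}"
            )
        # both streams must cover the same wall-clock span, to one IMU frame
        if abs(self.n_emg / EMG_RATE_HZ - self.n_imu / IMU_RATE_HZ) > 1.0 / IMU_RATE_HZ + 1e-12:
            raise ValidationError(
                f"EMG/IMU durations disagree: {self.n_emg} EMG samples "
                f"({self.n_emg / EMG_RATE_HZ:.3f} s) vs {self.n_imu} IMU samples "
                f"({self.n_imu / IMU_RATE_HZ:.3f} s)"
            )
        if self.n_imu:
            qn = np.linalg.norm(self.imu[:, :4], axis=1)
            bad = np.nonzero(np.abs(qn - 1.0) > 1e-3)[0]
            if bad.size:
                raise ValidationError(
                    f"quaternion not unit-norm at IMU row {bad[0]} (norm {qn[bad[0]]:.6f})"
                )


@dataclass
class SessionRecording:
    """One subject x repetition performance: left/right armband streams plus
    a 50 Hz gesture-label track aligned to the IMU frames."""

    left: ArmbandStream
    right: ArmbandStream
    labels: list[GestureLabel]
    subject_id: str
    repetition: int = 1

    def __post_init__(self):
        self.validate()

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        if self.repetition < 1:
            raise ValidationError("repetition must be >= 1")
        n = min(self.left.n_imu, self.right.n_imu)
        if self.left.n_imu != n or self.right.n_imu != n:
            raise ValidationError(
                f"left/right IMU lengths differ ({self.left.n_imu} vs {self.right.n_imu}); "
                "truncate to the minimum before constructing the session"
            )
        if len(self.labels) != n:
            raise ValidationError(
                f"label track has {len(self.labels)} frames, IMU streams have {n}"
            )
        for g in self.labels:
            if not isinstance(g, GestureLabel):
                raise ValidationError(f"label {g!r} is not a GestureLabel")

    def label_ordinals(self) -> np.ndarray:
        return labels_to_ordinals(self.labels)


@dataclass
class DatasetManifest:
    """Index of a simulated/recorded cohort: session directories (relative to
    the manifest location) and the subject roster."""

    sessions: list[str]
    subjects: list[str]
    schema_version: str = SCHEMA_VERSION
    root: Path | None = field(default=None, compare=False)

    def session_paths(self) -> list[Path]:
        base = self.root if self.root is not None else Path(".")
        return [base / s for s in self.sessions]

    def save(self, path: Path) -> Path:
        path = Path(path)
        payload = {
            "schema_version": self.schema_version,
            "subjects": list(self.subjects),
            "sessions": list(self.sessions),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: Path) -> "DatasetManifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        return cls(
            sessions=payload["sessions"],
            subjects=payload["subjects"],
            schema_version=payload.get("schema_version", SCHEMA_VERSION),
            root=path.parent,
        )


def _emg_times(n: int, t0: float) -> np.ndarray:
    return t0 + np.arange(n) / EMG_RATE_HZ


def _imu_times(n: int, t0: float) -> np.ndarray:
    return t0 + np.arange(n) / IMU_RATE_HZ


def write_session(session: SessionRecording, dir: Path) -> Path:
    """Write a session as six CSV files plus meta.json under ``dir``.

    Layout: ``{left,right}_emg.csv`` (t,ch1..ch8; integer channels),
    ``{left,right}_imu.csv`` (t,qw..gz; floats), ``labels.csv`` (frame,label),
    ``meta.json``.  Times are seconds from t0, printed to 6 decimals; IMU
    floats keep full double precision (repr round-trip).
    """
    dir = Path(dir)
    try:
        dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create session directory {dir}: {e}") from e

    for side, stream in (("left", session.left), ("right", session.right)):
        emg = pd.DataFrame(stream.emg.astype(np.int64), columns=list(EMG_COLUMNS))
        emg.insert(0, "t", np.round(_emg_times(stream.n_emg, stream.t0), 6))
        _write_csv(emg, dir / f"{side}_emg.csv", float_format="%.6f")

        imu = pd.DataFrame(stream.imu, columns=list(IMU_COLUMNS))
        imu.insert(0, "t", np.round(_imu_times(stream.n_imu, stream.t0), 6))
        _write_csv(imu, dir / f"{side}_imu.csv", float_format="%.17g")

    lab = pd.DataFrame(
        {"frame": np.arange(session.n_frames), "label": [g.name for g in session.labels]}
    )
    _write_csv(lab, dir / "labels.csv")

    meta = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": session.subject_id,
        "repetition": session.repetition,
        "t0": {"left": session.left.t0, "right": session.right.t0},
    }
    (dir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return dir


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    try:
        df.to_csv(path, index=False, **kw)
    except OSError as e:
        raise OSError(f"cannot write {path}: {e}") from e


_SESSION_FILES = (
    "meta.json",
    "left_emg.csv",
    "right_emg.csv",
    "left_imu.csv",
    "right_imu.csv",
    "labels.csv",
)


def read_session(dir: Path) -> SessionRecording:
    """Read and validate a session directory written by :func:`write_session`.

    Raises :class:`ValidationError` naming file, row and column on any
    contract violation (bad header, out-of-range EMG, unknown label, ...).
    """
    dir = Path(dir)
    for name in _SESSION_FILES:
        if not (dir / name).is_file():
            raise ValidationError(f"session directory {dir} is missing {name}")

    meta = json.loads((dir / "meta.json").read_text())

    streams = {}
    for side in ("left", "right"):
        emg_df = _read_checked(dir / f"{side}_emg.csv", ("t",) + EMG_COLUMNS)
        emg = emg_df[list(EMG_COLUMNS)].to_numpy()
        bad = np.argwhere((emg < -128) | (emg > 127))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"{side}_emg.csv row {r}: value {emg[r, c]} in column "
                f"{EMG_COLUMNS[c]} outside int8 range"
            )
        imu_df = _read_checked(dir / f"{side}_imu.csv", ("t",) + IMU_COLUMNS)
        t0 = meta.get("t0", {}).get(side, 0.0)
        streams[side] = ArmbandStream(
            emg=emg.astype(np.int16), imu=imu_df[list(IMU_COLUMNS)].to_numpy(), t0=t0
        )

    lab_df = _read_checked(dir / "labels.csv", ("frame", "label"))
    labels = []
    for i, code in enumerate(lab_df["label"]):
        try:
            labels.append(GestureLabel.from_code(str(code)))
        except ValueError as e:
            raise ValidationError(f"labels.csv row {i}: {e}") from None

    return SessionRecording(
        left=streams["left"],
        right=streams["right"],
        labels=labels,
        subject_id=str(meta["subject_id"]),
        repetition=int(meta["repetition"]),
    )


def _read_checked(path: Path, expected_cols: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ValidationError(f"cannot parse {path.name}: {e}") from e
    if tuple(df.columns) != expected_cols:
        raise ValidationError(
            f"{path.name}: malformed header {tuple(df.columns)}, expected {expected_cols}"
        )
    return df
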