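import numpy as np
import pytest

from scrubseq.core import ArmbandStream, GestureLabel, SessionRecording
from scrubseq.synthetic import (
    SimConfig,
    default_templates,
    draw_subject_profiles,
    simulate_cohort,
    simulate_session,
)


def make_session(
    duration_s: float = 5.0,
    labels: list[GestureLabel] | None = None,
    seed: int = 0,
    subject_id: str = "S01",
) -> SessionRecording:
    """Hand-rolled minimal valid session (independent of the simulator):
    random int8 EMG, identity-quaternion IMU."""
    rng = np.random.default_rng(seed)
    n_emg = int(duration_s * 200)
    n_imu = int(duration_s * 50)
    streams = []
    for _ in range(2):
        emg = rng.integers(-40, 40, size=(n_emg, 8)).astype(np.int16)
        imu = np.zeros((n_imu, 10))
        imu[:, 0] = 1.0  # unit quaternion (1,0,0,0)
        imu[:, 4:7] = rng.normal(0, 0.05, size=(n_imu, 3))
        imu[:, 6] += 9.81
        imu[:, 7:10] = rng.normal(0, 0.5, size=(n_imu, 3))
        streams.append(ArmbandStream(emg=emg, imu=imu))
    if labels is None:
        labels = [GestureLabel.G1] * n_imu
    return SessionRecording(
        left=streams[0], right=streams[1], labels=labels, subject_id=subject_id
    )


@pytest.fixture(scope="session")
def templates():
    return default_templates(1.0, seed=7)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_subjects=2, n_repetitions=1, seed=7)


@pytest.fixture(scope="session")
def synthetic_session(templates, sim_config):
    """One full simulated routine (9 gestures x 5 s)."""
    profile = draw_subject_profiles(sim_config)[0]
    return simulate_session(templates, profile, sim_config, repetition=1, seed=11)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 4-subject x 1-repetition cohort on disk (written once per run)."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SimConfig(n_subjects=4, n_repetitions=1, seed=5)
    manifest = simulate_cohort(cfg, out)
    return out, manifest
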