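"""Synthetic dual-armband cohorts emulating the hand-hygiene acquisition protocol.

The generator reproduces the statistical structure of the study design this
package targets: a cohort of subjects (default 17) each performing the nine
WHO gestures in routine order, each gesture held for 5 s, the full routine
repeated (default 3 times) with the armband slightly re-seated between
repetitions.  It is a stand-in for real recordings, not a physiological
simulator: surface EMG is modeled as amplitude-modulated band-limited
Gaussian noise (a standard sEMG surrogate), and arm motion as a small-angle
sinusoidal rotation about a gesture-specific axis.

What varies, and why:

* per-gesture templates — distinct per-channel EMG RMS patterns and motion
  parameters; the ``separation`` dial blends all templates toward their
  common mean, so 1.0 is the stated, fully distinct world and smaller values
  create genuinely harder discrimination problems;
* per-subject channel gains — lognormal, standing in for inter-subject
  differences in skin conductivity and muscle mass;
* per-repetition placement angle — the armband is an 8-electrode ring, so a
  rotation by a fraction of the 45-degree electrode spacing mixes adjacent
  EMG channels (circular fractional channel rotation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import (
    EMG_RATE_HZ,
    IMU_RATE_HZ,
    N_EMG_CHANNELS,
    ROUTINE_ORDER,
    ArmbandStream,
    DatasetManifest,
    GestureLabel,
    SessionRecording,
    write_session,
)

GRAVITY = 9.81  # m/s^2, +z in the world frame

# EMG band occupied by the surrogate signal (Hz); most surface-EMG power
# lives in 20-150 Hz, truncated here by the 100 Hz Nyquist of the armband.
EMG_BAND_HZ = (20.0, 95.0)
EMG_MODULATION_DEPTH = 0.1  # fractional RMS modulation at the motion frequency

# minimum pairwise cosine distance between flattened EMG activation patterns
# of distinct gestures, enforced at separation 1.0 by rejection sampling
MIN_TEMPLATE_COSINE_DIST = 0.1


@dataclass(frozen=True)
class GestureTemplate:
    """Idealized performance of one gesture: per-arm, per-channel EMG RMS
    amplitude (int8 units) plus a single dominant rubbing motion (axis,
    frequency, angular amplitude) per arm."""

    label: GestureLabel
    emg_activation: np.ndarray  # (2, 8) nonneg RMS amplitudes
    motion_axis: np.ndarray  # (2, 3) unit vectors
    motion_freq: float  # Hz
    motion_amp: float  # radians

    def __post_init__(self):
        act = np.asarray(self.emg_activation, dtype=float)
        axis = np.asarray(self.motion_axis, dtype=float)
        if act.shape != (2, N_EMG_CHANNELS) or not np.all(np.isfinite(act)) or act.min() < 0:
            raise ValueError("emg_activation must be a finite nonnegative (2, 8) array")
        if axis.shape != (2, 3):
            raise ValueError("motion_axis must be (2, 3)")
        if not (0 < self.motion_freq <= 10):
            raise ValueError("motion_freq must be in (0, 10] Hz")
        object.__setattr__(self, "emg_activation", act)
        object.__setattr__(
            self, "motion_axis", axis / np.linalg.norm(axis, axis=1, keepdims=True)
        )


@dataclass(frozen=True)
class SubjectProfile:
    """Subject-level nuisance parameters: multiplicative per-channel EMG
    gains, a per-repetition armband rotation offset, and the baseline EMG
    noise level (RMS, int8 units)."""

    subject_id: str
    channel_gain: np.ndarray  # (2, 8) positive
    placement_angles: np.ndarray  # (n_repetitions,) radians
    noise_floor: float = 2.0

    def __post_init__(self):
        g = np.asarray(self.channel_gain, dtype=float)
        if g.shape != (2, N_EMG_CHANNELS) or g.min() <= 0:
            raise ValueError("channel_gain must be positive with shape (2, 8)")
        object.__setattr__(self, "channel_gain", g)
        object.__setattr__(
            self, "placement_angles", np.asarray(self.placement_angles, dtype=float)
        )


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level design: 17 subjects x 3 repetitions x 9 gestures x 5 s
    by default, mirroring the acquisition protocol the generator emulates."""

    n_subjects: int = 17
    n_repetitions: int = 3
    gesture_duration_s: float = 5.0
    seed: int = 0
    separation: float = 1.0
    placement_max_angle: float = np.pi / 8
    gain_sigma: float = 0.25  # lognormal sigma of per-channel gains
    noise_floor: float = 2.0  # EMG RMS units (int8 counts)
    acc_noise_std: float = 0.05  # m/s^2
    gyro_noise_std: float = 0.5  # rad/s
    transition_fade_s: float = 0.0  # optional linear cross-fade between gestures

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_repetitions < 1:
            raise ValueError("n_subjects and n_repetitions must be >= 1")
        if self.gesture_duration_s <= 0:
            raise ValueError("gesture_duration_s must be > 0")
        if not (0 < self.separation <= 1):
            raise ValueError("separation must be in (0, 1]")


# ---------------------------------------------------------------------------
# templates


def default_templates(separation: float = 1.0, seed: int = 0) -> list[GestureTemplate]:
    """Nine gesture templates, one per label, deterministic in ``seed``.

    At separation 1.0 the raw seeded patterns are used; smaller values blend
    every template toward the across-gesture mean (EMG activations, motion
    frequency/amplitude, and motion axes alike), shrinking all pairwise
    distances proportionally.  Draws are rejected until the flattened EMG
    activations of distinct gestures keep a pairwise cosine distance >= 0.1
    before blending.
    """
    if not (0 < separation <= 1):
        raise ValueError("separation must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    for _attempt in range(64):
        # sparse-ish activation patterns: each gesture recruits 2-4 strong
        # channels per arm on top of a low base level
        base = 6.0
        patterns = rng.uniform(0.0, 1.0, size=(9, 2, N_EMG_CHANNELS)) ** 2
        acts = base + 38.0 * patterns
        flat = acts.reshape(9, -1)
        cos = (flat @ flat.T) / np.outer(
            np.linalg.norm(flat, axis=1), np.linalg.norm(flat, axis=1)
        )
        dist = 1.0 - cos
        if dist[np.triu_indices(9, 1)].min() >= MIN_TEMPLATE_COSINE_DIST:
            break
    freqs = rng.permutation(np.linspace(0.8, 2.8, 9))
    amps = rng.uniform(0.25, 0.45, size=9)
    axes = rng.normal(size=(9, 2, 3))
    axes /= np.linalg.norm(axes, axis=2, keepdims=True)

    # blend toward the mean world by (1 - separation)
    s = separation
    acts = (1 - s) * acts.mean(axis=0) + s * acts
    freqs = (1 - s) * freqs.mean() + s * freqs
    amps = (1 - s) * amps.mean() + s * amps
    mean_axis = axes.mean(axis=0)
    mean_axis /= np.linalg.norm(mean_axis, axis=1, keepdims=True)
    axes = (1 - s) * mean_axis + s * axes

    return [
        GestureTemplate(
            label=g,
            emg_activation=acts[i],
            motion_axis=axes[i],
            motion_freq=float(freqs[i]),
            motion_amp=float(amps[i]),
        )
        for i, g in enumerate(ROUTINE_ORDER)
    ]


def template_pairwise_cosine_distances(templates: list[GestureTemplate]) -> np.ndarray:
    """Condensed pairwise cosine distances of flattened EMG activations."""
    flat = np.stack([t.emg_activation.ravel() for t in templates])
    norm = np.linalg.norm(flat, axis=1)
    cos = (flat @ flat.T) / np.outer(norm, norm)
    return (1.0 - cos)[np.triu_indices(len(templates), 1)]


# ---------------------------------------------------------------------------
# subjects


def draw_subject_profiles(config: SimConfig) -> list[SubjectProfile]:
    """Draw per-subject gains and per-repetition placement angles, seeded by
    the cohort seed and the subject index (stable under changes in
    n_subjects ordering)."""
    profiles = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1, i]))
        gains = rng.lognormal(mean=0.0, sigma=config.gain_sigma, size=(2, N_EMG_CHANNELS))
        angles = rng.uniform(
            -config.placement_max_angle, config.placement_max_angle, size=config.n_repetitions
        )
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                channel_gain=gains,
                placement_angles=angles,
                noise_floor=config.noise_floor,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# signal synthesis


def _bandlimited_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Zero-mean, unit-variance band-limited Gaussian noise along axis 0
    (4th-order Butterworth band-pass, 20-95 Hz at the 200 Hz EMG rate)."""
    sos = sps.butter(
        4, EMG_BAND_HZ, btype="bandpass", fs=EMG_RATE_HZ, output="sos"
    )
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=0)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0, keepdims=True)) / sd


def _rotate_channels(rms: np.ndarray, angle: float) -> np.ndarray:
    """Circularly interpolate the 8-channel RMS pattern by a fractional
    channel shift of angle / (2*pi/8): linear mix of adjacent electrodes."""
    shift = angle / (2 * np.pi / N_EMG_CHANNELS)
    k = int(np.floor(shift))
    frac = shift - k
    rolled = np.roll(rms, k, axis=-1)
    rolled_next = np.roll(rms, k + 1, axis=-1)
    return (1 - frac) * rolled + frac * rolled_next


def _quat_from_axis_angle(axis: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Unit quaternions (n, 4) for rotations of theta (n,) about a fixed axis."""
    half = theta / 2.0
    q = np.empty((theta.size, 4))
    q[:, 0] = np.cos(half)
    q[:, 1:] = np.sin(half)[:, None] * axis[None, :]
    return q


def _rotation_matrices(axis: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices (n, 3, 3) about a fixed unit axis."""
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    I = np.eye(3)
    st, ct = np.sin(theta), np.cos(theta)
    return I[None] + st[:, None, None] * K[None] + (1 - ct)[:, None, None] * (K @ K)[None]


def _simulate_arm(
    arm: int,
    templates: list[GestureTemplate],
    profile: SubjectProfile,
    config: SimConfig,
    placement_angle: float,
    rng: np.random.Generator,
) -> ArmbandStream:
    n_per = int(round(config.gesture_duration_s * EMG_RATE_HZ))
    m_per = int(round(config.gesture_duration_s * IMU_RATE_HZ))
    n_total, m_total = n_per * len(templates), m_per * len(templates)

    # --- EMG: gain x placement-mixed template RMS x (1 + 0.1 sin) x noise
    rms_track = np.empty((n_total, N_EMG_CHANNELS))
    mod_track = np.empty(n_total)
    t_emg = np.arange(n_per) / EMG_RATE_HZ
    for i, tpl in enumerate(templates):
        mixed = _rotate_channels(tpl.emg_activation[arm], placement_angle)
        sl = slice(i * n_per, (i + 1) * n_per)
        rms_track[sl] = mixed[None, :]
        mod_track[sl] = 1.0 + EMG_MODULATION_DEPTH * np.sin(
            2 * np.pi * tpl.motion_freq * t_emg
        )
    if config.transition_fade_s > 0:
        rms_track = _crossfade(rms_track, n_per, int(config.transition_fade_s * EMG_RATE_HZ))
    carrier = _bandlimited_noise(rng, (n_total, N_EMG_CHANNELS))
    emg = profile.channel_gain[arm][None, :] * rms_track * mod_track[:, None] * carrier
    if profile.noise_floor > 0:
        emg = emg + profile.noise_floor * _bandlimited_noise(rng, (n_total, N_EMG_CHANNELS))
    emg = np.clip(np.rint(emg), -128, 127).astype(np.int16)

    # --- IMU: sinusoidal rotation about the gesture motion axis
    imu = np.empty((m_total, 10))
    t_imu = np.arange(m_per) / IMU_RATE_HZ
    phase = rng.uniform(0, 2 * np.pi, size=len(templates))
    for i, tpl in enumerate(templates):
        axis = tpl.motion_axis[arm]
        w = 2 * np.pi * tpl.motion_freq
        theta = tpl.motion_amp * np.sin(w * t_imu + phase[i])
        theta_dot = tpl.motion_amp * w * np.cos(w * t_imu + phase[i])
        sl = slice(i * m_per, (i + 1) * m_per)
        imu[sl, 0:4] = _quat_from_axis_angle(axis, theta)
        # gravity seen in the sensor frame: R(t)^T g, plus a tangential
        # sinusoid from the rubbing motion itself
        R = _rotation_matrices(axis, theta)
        g_sensor = np.einsum("nij,j->ni", R.transpose(0, 2, 1), np.array([0.0, 0.0, GRAVITY]))
        tang = np.cross(axis, np.array([0.0, 0.0, 1.0]))
        tang_norm = np.linalg.norm(tang)
        if tang_norm > 1e-12:
            tang = tang / tang_norm
        a_tang = (tpl.motion_amp * w**2) * np.sin(w * t_imu + phase[i])
        imu[sl, 4:7] = g_sensor + a_tang[:, None] * tang[None, :]
        imu[sl, 7:10] = theta_dot[:, None] * axis[None, :]
    imu[:, 4:7] += config.acc_noise_std * rng.standard_normal((m_total, 3))
    imu[:, 7:10] += config.gyro_noise_std * rng.standard_normal((m_total, 3))

    return ArmbandStream(emg=emg, imu=imu, t0=0.0)


def _crossfade(track: np.ndarray, seg_len: int, fade: int) -> np.ndarray:
    """Linear cross-fade of the piecewise-constant RMS track across segment
    boundaries (fade samples centered on each boundary)."""
    if fade <= 1:
        return track
    out = track.copy()
    n = track.shape[0]
    for b in range(seg_len, n, seg_len):
        lo, hi = max(b - fade // 2, 0), min(b + fade // 2, n)
        w = np.linspace(0.0, 1.0, hi - lo)[:, None]
        out[lo:hi] = (1 - w) * track[lo - 1] + w * track[min(hi, n - 1)]
    return out


def simulate_session(
    templates: list[GestureTemplate],
    profile: SubjectProfile,
    config: SimConfig,
    repetition: int = 1,
    seed: int | None = None,
) -> SessionRecording:
    """Simulate one routine performance: the nine gestures in routine order,
    each held for ``gesture_duration_s``, on both arms.

    ``seed`` defaults to a value derived from (config.seed, subject, rep);
    the session is a pure function of its arguments.
    """
    if repetition < 1 or repetition > config.n_repetitions:
        raise ValueError(f"repetition {repetition} outside 1..{config.n_repetitions}")
    if len(templates) != 9 or {t.label for t in templates} != set(ROUTINE_ORDER):
        raise ValueError("templates must cover the 9 gestures exactly once")
    templates = sorted(templates, key=lambda t: t.label.ordinal)
    if seed is None:
        seed = int(
            np.random.default_rng(
                np.random.SeedSequence(
                    [int(config.seed), 2, int(profile.subject_id.lstrip("S") or 0), repetition]
                )
            ).integers(2**31)
        )
    angle = float(profile.placement_angles[repetition - 1])
    rng_l = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    rng_r = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    left = _simulate_arm(0, templates, profile, config, angle, rng_l)
    right = _simulate_arm(1, templates, profile, config, angle, rng_r)
    m_per = int(round(config.gesture_duration_s * IMU_RATE_HZ))
    labels = [t.label for t in templates for _ in range(m_per)]
    return SessionRecording(
        left=left,
        right=right,
        labels=labels,
        subject_id=profile.subject_id,
        repetition=repetition,
    )


def simulate_cohort(config: SimConfig, out_dir: Path) -> DatasetManifest:
    """Simulate and write a full cohort; returns the saved manifest.

    Session directories are named ``<subject>_r<rep>``; the manifest
    (``manifest.json``) lists them relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    templates = default_templates(config.separation, seed=config.seed)
    profiles = draw_subject_profiles(config)
    sessions = []
    for profile in profiles:
        for rep in range(1, config.n_repetitions + 1):
            sess = simulate_session(templates, profile, config, repetition=rep)
            name = f"{profile.subject_id}_r{rep}"
            write_session(sess, out_dir / name)
            sessions.append(name)
    manifest = DatasetManifest(
        sessions=sessions, subjects=[p.subject_id for p in profiles], root=out_dir
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
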