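"""Synthetic multi-subject marker-trajectory generator.

Emulates a lower-body optical-capture session: 10 markers (thigh, shank,
two ankle markers and tiptoe on each side) sampled at 5 Hz while the
subject walks along the x axis.  Each subject is a planar two-link
(thigh-shank) kinematic chain per leg driven by sinusoidal joint angles;
the legs are in antiphase.  Per-subject anthropometry (drawn from the
height range 1.44-1.78 m), walking speed, cadence and gait phase give each
subject a distinct distance/velocity signature.  Gaussian sensor noise and
sporadic large outlier displacements emulate tracking imperfections.

This is a statistical stand-in for real capture data: it provides the
structure the recognition pipeline needs (distinguishable subjects,
realistic frame counts, occasional outliers), not biomechanical fidelity.
All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trajectory import DEFAULT_TAU, GaitDataset, GaitTrajectory

#: Anthropometric segment-length fractions of body height (standard
#: biomechanics tables, rounded).
THIGH_FRACTION = 0.245
SHANK_FRACTION = 0.246
FOOT_FRACTION = 0.152
HIP_HEIGHT_FRACTION = 0.530


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject anthropometry and gait-style parameters (SI units)."""

    thigh_length: float
    shank_length: float
    foot_length: float
    hip_height: float
    stride_length: float
    gait_frequency: float  # strides per second
    walking_speed: float
    phase_offset: float  # radians
    lateral_offset: float  # half hip width, meters
    knee_flexion_amplitude: float  # radians

    def __post_init__(self) -> None:
        for name in ("thigh_length", "shank_length", "foot_length", "hip_height",
                     "stride_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.walking_speed < 0:  # 0 allowed: standing still is a valid degenerate pose
            raise ValueError("walking_speed must be nonnegative")
        if not 0.0 <= self.gait_frequency <= 1.5:
            raise ValueError("gait_frequency must lie in [0, 1.5] Hz")

    @property
    def thigh_swing_amplitude(self) -> float:
        """Hip swing (radians) consistent with the stride length."""
        leg = self.thigh_length + self.shank_length
        return float(np.arcsin(np.clip(self.stride_length / (4.0 * leg), 0.02, 0.95)))


@dataclass(frozen=True)
class SimulationConfig:
    """Session-level settings: cohort size, recording length, noise, seed."""

    n_subjects: int = 10
    n_frames: int = 120
    tau: float = DEFAULT_TAU
    noise_std: float = 0.02  # meters; marker jitter incl. soft-tissue artefact
    outlier_prob: float = 0.0  # per marker-frame
    outlier_magnitude: float = 0.5  # meters
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must lie in [0, 1]")
        if self.noise_std < 0 or self.outlier_magnitude < 0:
            raise ValueError("noise_std and outlier_magnitude must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def sample_population(n_subjects: int, seed: int) -> list[SubjectParams]:
    """Draw a cohort of subjects; deterministic given the seed.

    Heights are uniform on 1.44-1.78 m; walking speed uniform on
    0.9-1.3 m/s; cadence uniform on 0.7-1.1 strides/s; gait phase uniform on
    the circle.  Segment lengths follow standard height fractions with a
    little individual scatter.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        height = rng.uniform(1.44, 1.78)
        jitter = 1.0 + rng.normal(0.0, 0.02, size=3)
        speed = rng.uniform(0.9, 1.3)
        freq = rng.uniform(0.7, 1.1)
        subjects.append(
            SubjectParams(
                thigh_length=height * THIGH_FRACTION * jitter[0],
                shank_length=height * SHANK_FRACTION * jitter[1],
                foot_length=height * FOOT_FRACTION * jitter[2],
                hip_height=height * HIP_HEIGHT_FRACTION,
                stride_length=speed / freq,
                gait_frequency=freq,
                walking_speed=speed,
                phase_offset=rng.uniform(0.0, 2.0 * np.pi),
                lateral_offset=rng.uniform(0.08, 0.12),
                knee_flexion_amplitude=rng.uniform(0.4, 0.7),
            )
        )
    return subjects


def _leg_markers(
    subject: SubjectParams, t: np.ndarray, hip_x: np.ndarray, side: float, phase: float
) -> np.ndarray:
    """Marker positions for one leg; shape (T, 5, 3).

    Planar forward kinematics in the sagittal (x-z) plane: the thigh angle
    (from vertical) and knee flexion follow sinusoids; five markers are
    placed along the chain (mid-thigh, mid-shank, two ankle markers,
    tiptoe) at a fixed lateral (y) offset.
    """
    omega = 2.0 * np.pi * subject.gait_frequency
    arg = omega * t + phase
    theta = subject.thigh_swing_amplitude * np.sin(arg)
    # knee flexes most during swing (quarter-cycle lead), never hyperextends
    knee = subject.knee_flexion_amplitude * 0.5 * (1.0 + np.sin(arg + 0.5 * np.pi))
    theta_shank = theta - knee
    hip = np.stack(
        [hip_x, np.full_like(hip_x, side * subject.lateral_offset),
         np.full_like(hip_x, subject.hip_height)], axis=-1,
    )
    thigh_dir = np.stack([np.sin(theta), np.zeros_like(theta), -np.cos(theta)], axis=-1)
    shank_dir = np.stack(
        [np.sin(theta_shank), np.zeros_like(theta), -np.cos(theta_shank)], axis=-1
    )
    knee_pos = hip + subject.thigh_length * thigh_dir
    ankle_pos = knee_pos + subject.shank_length * shank_dir
    # foot pitch follows the shank with a damped amplitude
    pitch = 0.3 * theta_shank
    foot_dir = np.stack([np.cos(pitch), np.zeros_like(pitch), np.sin(pitch)], axis=-1)
    markers = np.stack(
        [
            hip + 0.55 * subject.thigh_length * thigh_dir,          # thigh
            knee_pos + 0.45 * subject.shank_length * shank_dir,     # shank
            knee_pos + 0.90 * subject.shank_length * shank_dir,     # ankle (shin-side)
            ankle_pos + np.array([0.04, 0.0, -0.02]),               # ankle (foot-side)
            ankle_pos + subject.foot_length * foot_dir,             # tiptoe
        ],
        axis=1,
    )
    return markers


def simulate_trajectory(
    subject: SubjectParams,
    n_frames: int,
    config: SimulationConfig,
    subject_label: str = "s00",
    rng: np.random.Generator | None = None,
) -> GaitTrajectory:
    """Simulate one recording of ``n_frames`` frames for one subject.

    The hips advance along x at the subject's walking speed; left and right
    legs are driven in antiphase.  i.i.d. Gaussian noise of the configured
    standard deviation is added to every coordinate.  Deterministic given
    the generator (or ``config.seed`` when none is passed).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.arange(n_frames) * config.tau
    hip_x = subject.walking_speed * t
    left = _leg_markers(subject, t, hip_x, side=+1.0, phase=subject.phase_offset)
    right = _leg_markers(subject, t, hip_x, side=-1.0, phase=subject.phase_offset + np.pi)
    pos = np.concatenate([left, right], axis=1)  # (T, 10, 3)
    if config.noise_std > 0:
        pos = pos + rng.normal(0.0, config.noise_std, size=pos.shape)
    return GaitTrajectory.from_array(pos, subject_label=subject_label, tau=config.tau)


def inject_outliers(
    traj: GaitTrajectory, p: float, magnitude: float, seed: int
) -> GaitTrajectory:
    """Displace each marker-frame by +/-magnitude on a random axis w.p. ``p``.

    Emulates sporadic tracking failures (marker swaps, reflections).  The
    expected number of corrupted marker-frames is p * T * 10.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pos = traj.positions.copy()
    T, M, _ = pos.shape
    hit = rng.random((T, M)) < p
    axes = rng.integers(0, 3, size=(T, M))
    signs = rng.choice([-1.0, 1.0], size=(T, M))
    tt, mm = np.nonzero(hit)
    pos[tt, mm, axes[tt, mm]] += signs[tt, mm] * magnitude
    return GaitTrajectory.from_array(
        pos, subject_label=traj.subject_label, tau=traj.tau,
        frame_indices=np.array([f.frame_index for f in traj.frames]),
    )


def simulate_dataset(
    config: SimulationConfig,
    recordings_per_subject: int = 1,
    frames_per_recording: int | None = None,
    population: list[SubjectParams] | None = None,
) -> GaitDataset:
    """Simulate a full cohort dataset; deterministic given ``config.seed``.

    Each subject gets ``recordings_per_subject`` independent recordings of
    ``frames_per_recording`` frames (default ``config.n_frames``).  Outliers
    are injected when ``config.outlier_prob > 0``.
    """
    frames = frames_per_recording or config.n_frames
    if population is None:
        population = sample_population(config.n_subjects, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    trajectories = []
    for s, subject in enumerate(population):
        label = f"s{s + 1:02d}"
        for _ in range(recordings_per_subject):
            traj = simulate_trajectory(subject, frames, config, subject_label=label, rng=rng)
            if config.outlier_prob > 0:
                traj = inject_outliers(
                    traj, config.outlier_prob, config.outlier_magnitude,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            trajectories.append(traj)
    return GaitDataset(trajectories=trajectories)


def make_benchmark(
    n_subjects: int = 10,
    train_frames: int = 120,
    test_frames: int = 60,
    test_recordings: int = 3,
    seed: int = 0,
    noise_std: float = 0.02,
    outlier_prob: float = 0.0,
    outlier_magnitude: float = 0.5,
) -> tuple[GaitDataset, GaitDataset]:
    """Matched train/test datasets sharing one simulated cohort.

    Frame counts follow the usual session design (about twice as many
    training frames as test frames per subject).  The same subjects appear
    in both splits but every recording is an independent noise realization.
    """
    population = sample_population(n_subjects, seed)
    base = SimulationConfig(
        n_subjects=n_subjects, tau=DEFAULT_TAU, noise_std=noise_std,
        outlier_prob=outlier_prob, outlier_magnitude=outlier_magnitude,
    )
    train = simulate_dataset(
        replace(base, n_frames=train_frames, seed=seed),
        recordings_per_subject=1, population=population,
    )
    test = simulate_dataset(
        replace(base, n_frames=test_frames, seed=seed + 10_000),
        recordings_per_subject=test_recordings, population=population,
    )
    return train, test
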