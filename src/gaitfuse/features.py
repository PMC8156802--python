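"""Frame-level gait features: pairwise marker distances and x-axis speeds.

Each motion frame t yields a 55-dimensional vector z^t = {d^t; v^t}:

* d^t — the 45 strictly-upper-triangle entries of the symmetric 10x10
  Euclidean distance matrix between markers (row-major order d_{1,2},
  d_{1,3}, ..., d_{9,10}).  Relative distances capture both body shape and
  the momentary limb configuration, and are invariant to where in the lab
  the subject walks and which way they face.
* v^t — forward (x-axis) velocity of each marker, (x_i^{t+1} - x_i^t)/tau,
  signed.  Walking speed is a known biometric correlate.

The last frame of a recording has no forward difference, so a T-frame
trajectory yields T-1 feature rows.  Features are z-scored with statistics
fitted on the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .trajectory import GaitTrajectory, InsufficientDataError, MarkerFrame

N_DISTANCES = 45
N_VELOCITIES = 10
N_FEATURES = N_DISTANCES + N_VELOCITIES


def n_pair_features(n_markers: int) -> int:
    """Feature count for an n-marker subset: n(n-1)/2 distances + n speeds."""
    return n_markers * (n_markers - 1) // 2 + n_markers


def feature_names(n_markers: int = 10) -> list[str]:
    names = [
        f"d_{i + 1:02d}_{j + 1:02d}"
        for i in range(n_markers)
        for j in range(i + 1, n_markers)
    ]
    names += [f"v_{i + 1:02d}" for i in range(n_markers)]
    return names


def pairwise_distance_features(frame: MarkerFrame) -> np.ndarray:
    """Strictly-upper-triangle pairwise distances of one frame (length 45).

    ``scipy.spatial.distance.pdist`` already emits the condensed upper
    triangle in row-major order, which is exactly the required flattening.
    """
    return pdist(frame.positions)


def velocity_features(
    frame_t: MarkerFrame, frame_next: MarkerFrame, tau: float
) -> np.ndarray:
    """Signed x-axis velocity of each marker between consecutive frames."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return (frame_next.positions[:, 0] - frame_t.positions[:, 0]) / tau


def extract_feature_sequence(traj: GaitTrajectory) -> np.ndarray:
    """Per-frame feature matrix of shape (T-1, 55).

    Row t concatenates the distance features of frame t with the forward
    velocity computed from frames (t, t+1).
    """
    pos = traj.positions  # (T, M, 3)
    T = pos.shape[0]
    if T < 2:
        raise InsufficientDataError("need at least 2 frames to form features")
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    dist = np.sqrt(np.einsum("tijk,tijk->tij", diff, diff))
    iu, ju = np.triu_indices(pos.shape[1], k=1)
    distances = dist[:, iu, ju]  # (T, n_pairs) row-major upper triangle
    velocities = (pos[1:, :, 0] - pos[:-1, :, 0]) / traj.tau  # (T-1, M)
    return np.hstack([distances[:-1], velocities])


@dataclass
class NormalizerStats:
    """Per-feature z-score statistics fitted on the training split."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.mean.shape != self.scale.shape:
            raise ValueError("mean and scale must have the same length")
        if np.any(self.scale <= 0):
            raise ValueError("scales must be positive")


def fit_normalizer(train_features: np.ndarray) -> NormalizerStats:
    """Fit per-column mean and sample (n-1) standard deviation.

    Zero-variance columns get scale 1 (and a warning) so they normalize to
    a constant 0 instead of NaN.
    """
    X = np.asarray(train_features, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit a normalizer on an empty matrix")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    degenerate = scale == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s); scale set to 1",
            stacklevel=2,
        )
        scale = np.where(degenerate, 1.0, scale)
    return NormalizerStats(mean=mean, scale=scale)


def apply_normalizer(stats: NormalizerStats, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.shape[-1] != stats.mean.shape[0]:
        raise ValueError(
            f"feature count {X.shape[-1]} does not match fitted stats "
            f"({stats.mean.shape[0]})"
        )
    return (X - stats.mean) / stats.scale
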