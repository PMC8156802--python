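"""Trajectory data model and plain-text marker-trajectory I/O.

A gait recording is an ordered sequence of frames, each holding the 3-D
positions (in meters) of 10 lower-body optical markers sampled at a fixed
interval ``tau`` (default 0.2 s, i.e. 5 Hz).  The on-disk exchange format is
a small CSV dialect::

    # tau=0.2 subject=s01
    frame,m01_x,m01_y,m01_z,...,m10_x,m10_y,m10_z
    0,0.1234,...
    1,...

The first line is an optional comment carrying the sampling interval and the
subject label; one data row per frame, full float precision, '.' decimal
separator.  Marker ordering is fixed by convention (left side then right
side): thigh, shank, ankle (shin-side), ankle (foot-side), tiptoe.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np

N_MARKERS = 10
N_COORDS = 3
DEFAULT_TAU = 0.2

#: Documented marker ordering (an arbitrary but fixed convention; any
#: consistent ordering works as long as train and test agree).
MARKER_NAMES = (
    "left_thigh",
    "left_shank",
    "left_ankle_shin",
    "left_ankle_foot",
    "left_tiptoe",
    "right_thigh",
    "right_shank",
    "right_ankle_shin",
    "right_ankle_foot",
    "right_tiptoe",
)


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (wrong columns, bad cell, ...)."""


class InsufficientDataError(ValueError):
    """Fewer frames than the minimum the pipeline needs (2)."""


def _column_names(n_markers: int = N_MARKERS) -> list[str]:
    cols = ["frame"]
    for m in range(1, n_markers + 1):
        for ax in ("x", "y", "z"):
            cols.append(f"m{m:02d}_{ax}")
    return cols


@dataclass(frozen=True)
class MarkerFrame:
    """Positions of the 10 markers in one motion frame.

    Parameters
    ----------
    positions
        Array of shape (10, 3): rows follow :data:`MARKER_NAMES`, columns
        are x, y, z in meters.
    frame_index
        Non-negative frame number within the recording.
    """

    positions: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        # the standard capture setup has 10 markers, but reduced marker
        # subsets (>= 2, so pairwise distances exist) are valid analyses
        if pos.ndim != 2 or pos.shape[1] != N_COORDS or pos.shape[0] < 2:
            raise ValueError(
                f"expected (n_markers >= 2, {N_COORDS}) positions, got {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("marker positions must be finite")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        object.__setattr__(self, "positions", pos)


@dataclass
class GaitTrajectory:
    """One gait recording: ordered frames plus subject label and ``tau``."""

    subject_label: str
    frames: list[MarkerFrame]
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if len(self.frames) < 2:
            raise InsufficientDataError(
                "a trajectory needs at least 2 frames (velocities use consecutive pairs)"
            )
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        counts = {f.positions.shape[0] for f in self.frames}
        if len(counts) != 1:
            raise ValueError("all frames must carry the same marker count")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """Stacked positions, shape (T, 10, 3)."""
        return np.stack([f.positions for f in self.frames])

    @property
    def n_markers(self) -> int:
        return self.frames[0].positions.shape[0]

    @classmethod
    def from_array(
        cls,
        positions: np.ndarray,
        subject_label: str,
        tau: float = DEFAULT_TAU,
        frame_indices: np.ndarray | None = None,
    ) -> "GaitTrajectory":
        """Build a trajectory from a (T, 10, 3) position array."""
        positions = np.asarray(positions, dtype=float)
        if frame_indices is None:
            frame_indices = np.arange(positions.shape[0])
        frames = [
            MarkerFrame(positions=p, frame_index=int(i))
            for p, i in zip(positions, frame_indices)
        ]
        return cls(subject_label=subject_label, frames=frames, tau=tau)


@dataclass
class GaitDataset:
    """A collection of recordings with an ordered list of subject labels."""

    trajectories: list[GaitTrajectory]
    class_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_list:
            seen: dict[str, None] = {}
            for t in self.trajectories:
                seen.setdefault(t.subject_label, None)
            self.class_list = list(seen)
        labels = set(self.class_list)
        for t in self.trajectories:
            if t.subject_label not in labels:
                raise ValueError(
                    f"trajectory label {t.subject_label!r} not in class_list"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def labels(self) -> list[str]:
        return [t.subject_label for t in self.trajectories]


_HEADER_RE = re.compile(r"#\s*tau=(?P<tau>[0-9.eE+-]+)(?:\s+subject=(?P<subject>\S+))?")


def write_trajectory_file(traj: GaitTrajectory, path) -> None:
    """Write a trajectory in the CSV dialect, at full float precision."""
    if traj.n_markers != N_MARKERS:
        raise ValueError(
            f"the trajectory CSV dialect carries exactly {N_MARKERS} markers; "
            f"got {traj.n_markers}"
        )
    cols = _column_names()
    for frame in traj.frames:
        if not np.all(np.isfinite(frame.positions)):
            raise ValueError(
                f"frame {frame.frame_index} holds non-finite coordinates; refusing to write"
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# tau={traj.tau!r} subject={traj.subject_label}\n")
        writer = csv.writer(fh)
        writer.writerow(cols)
        for frame in traj.frames:
            row = [frame.frame_index] + [repr(float(v)) for v in frame.positions.ravel()]
            writer.writerow(row)


def read_trajectory_file(path, subject_label: str | None = None) -> GaitTrajectory:
    """Read a trajectory CSV; see the module docstring for the dialect.

    ``subject_label`` overrides the label stored in the header comment
    (a file with no header comment defaults to tau=0.2 and label "unknown").
    """
    tau = DEFAULT_TAU
    label = "unknown"
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = _HEADER_RE.match(first)
            if m:
                tau = float(m.group("tau"))
                if m.group("subject"):
                    label = m.group("subject")
            header_line = fh.readline()
        else:
            header_line = first
        expected = _column_names()
        got = next(csv.reader([header_line])) if header_line else []
        got = [c.strip() for c in got]
        if got != expected:
            missing = [c for c in expected if c not in got]
            extra = [c for c in got if c not in expected]
            bad = missing[0] if missing else (extra[0] if extra else "<order>")
            raise TrajectoryFormatError(
                f"bad column layout in {path}: offending column {bad!r} "
                f"(missing={missing}, unexpected={extra})"
            )
        frames: list[MarkerFrame] = []
        for rowno, row in enumerate(csv.reader(fh), start=3):
            if not row:
                continue
            if len(row) != len(expected):
                raise TrajectoryFormatError(
                    f"row {rowno} of {path} has {len(row)} cells, expected {len(expected)}"
                )
            try:
                idx = int(float(row[0]))
                coords = np.array([float(v) for v in row[1:]], dtype=float)
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"non-numeric cell in row {rowno} of {path}: {exc}"
                ) from None
            frames.append(
                MarkerFrame(positions=coords.reshape(N_MARKERS, N_COORDS), frame_index=idx)
            )
    if len(frames) < 2:
        raise InsufficientDataError(f"{path} holds {len(frames)} frames; need at least 2")
    if subject_label is not None:
        label = subject_label
    return GaitTrajectory(subject_label=label, frames=frames, tau=tau)
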