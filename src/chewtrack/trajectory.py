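"""Keypoint trajectory containers and plain-text I/O.

A trajectory is the per-frame output of a pose detector watching a
ruminating animal: one nose and one mouth keypoint per video frame, in
image-pixel coordinates (origin top-left, y downward), plus timing
metadata.  Frames where the detector found nothing (the animal turned its
head away, occlusion, ...) are kept in the sequence but flagged
``detected=False`` so downstream gap policies can decide what to do with
them.

File format: a plain CSV with columns ``frame``, optional ``time_s``,
``nose_x``, ``nose_y``, optional ``nose_conf``, ``mouth_x``, ``mouth_y``,
optional ``mouth_conf``.  Empty coordinate cells mean "not detected".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "Keypoint",
    "FramePose",
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "read_manual_counts",
]

PathLike = Union[str, Path]


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory data."""


@dataclass(frozen=True)
class Keypoint:
    """A single detected keypoint in image pixels.

    ``confidence`` is the detector score in [0, 1]; ``visible`` carries the
    visibility flag used by OKS-style evaluation.
    """

    x: float
    y: float
    confidence: float = 1.0
    visible: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise TrajectoryError(
                f"confidence must lie in [0, 1], got {self.confidence!r}"
            )
        if self.visible and (math.isnan(self.x) or math.isnan(self.y)):
            raise TrajectoryError("visible keypoint requires finite coordinates")


@dataclass(frozen=True)
class FramePose:
    """Nose/mouth keypoints for one video frame.

    ``detected`` is False exactly when either keypoint is missing.
    ``time_s`` defaults to ``frame_index / fps`` when no explicit time
    column is present in the source file.
    """

    frame_index: int
    time_s: float
    nose: Optional[Keypoint] = None
    mouth: Optional[Keypoint] = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise TrajectoryError(f"frame_index must be >= 0, got {self.frame_index}")

    @property
    def detected(self) -> bool:
        return self.nose is not None and self.mouth is not None


@dataclass
class Trajectory:
    """An ordered sequence of frame poses at a fixed nominal frame rate."""

    frames: list[FramePose] = field(default_factory=list)
    fps: float = 30.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise TrajectoryError(f"fps must be positive, got {self.fps}")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise TrajectoryError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[FramePose]:
        return iter(self.frames)

    @property
    def n_detected(self) -> int:
        return sum(1 for f in self.frames if f.detected)


_REQUIRED_COLS = ("frame", "nose_x", "nose_y", "mouth_x", "mouth_y")


def _cell_keypoint(row: pd.Series, prefix: str) -> Optional[Keypoint]:
    x = row[f"{prefix}_x"]
    y = row[f"{prefix}_y"]
    if pd.isna(x) or pd.isna(y):
        return None
    conf = row.get(f"{prefix}_conf", 1.0)
    if pd.isna(conf):
        conf = 1.0
    return Keypoint(float(x), float(y), confidence=float(conf))


def read_trajectory(path: PathLike, fps_override: Optional[float] = None) -> Trajectory:
    """Read a trajectory CSV, sorting by frame index.

    Rows with any missing keypoint coordinate become undetected frames.
    Missing confidence defaults to 1.0.  Duplicate frame indices are a
    validation error; non-numeric cells raise a parse error naming the row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise TrajectoryError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing required columns {missing}")

    numeric_cols = [c for c in df.columns if c in
                    ("frame", "time_s", "nose_x", "nose_y", "nose_conf",
                     "mouth_x", "mouth_y", "mouth_conf")]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise TrajectoryError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        df[col] = coerced

    if df["frame"].duplicated().any():
        dup = int(df["frame"][df["frame"].duplicated()].iloc[0])
        raise TrajectoryError(f"{path}: duplicate frame_index {dup}")

    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    fps = float(fps_override) if fps_override is not None else 30.0

    frames: list[FramePose] = []
    for _, row in df.iterrows():
        fi = int(row["frame"])
        if "time_s" in df.columns and not pd.isna(row["time_s"]):
            t = float(row["time_s"])
        else:
            t = fi / fps
        frames.append(
            FramePose(
                frame_index=fi,
                time_s=t,
                nose=_cell_keypoint(row, "nose"),
                mouth=_cell_keypoint(row, "mouth"),
            )
        )
    return Trajectory(frames=frames, fps=fps, source_id=path.stem)


def write_trajectory(traj: Trajectory, path: PathLike) -> Path:
    """Write a trajectory CSV such that ``read_trajectory`` round-trips it.

    Missing keypoints are written as empty cells.  An empty trajectory
    produces a header-only file.
    """
    path = Path(path)
    rows = []
    for f in traj.frames:
        rows.append(
            {
                "frame": f.frame_index,
                "time_s": f.time_s,
                "nose_x": f.nose.x if f.nose else None,
                "nose_y": f.nose.y if f.nose else None,
                "nose_conf": f.nose.confidence if f.nose else None,
                "mouth_x": f.mouth.x if f.mouth else None,
                "mouth_y": f.mouth.y if f.mouth else None,
                "mouth_conf": f.mouth.confidence if f.mouth else None,
            }
        )
    cols = ["frame", "time_s", "nose_x", "nose_y", "nose_conf",
            "mouth_x", "mouth_y", "mouth_conf"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def read_manual_counts(path: PathLike) -> pd.DataFrame:
    """Read a manual chew-count validation table.

    Expected columns: ``video_id``, ``duration_s``, ``assessed`` (the
    pipeline's count), ``measured`` (the human tally).
    """
    df = pd.read_csv(path)
    required = ("video_id", "assessed", "measured")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise TrajectoryError(f"{path}: no data rows")
    return df
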