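"""Rumination motion curve: nose-mouth distance series and denoising.

One open-close jaw cycle shows up as one oscillation of the Euclidean
distance between the nose and mouth keypoints, so the per-frame distance
series is the signal everything downstream works on.  Detection dropouts
(head turns) leave holes: short holes are linearly interpolated, long ones
split the series into independent segments so no synthetic motion is
fabricated across a gap.

Denoising is zero-phase by construction — the chew counter keys on peak
*positions*, so the filter must not shift them.  The default is a
forward-backward Butterworth low-pass; a sliding-window median filter is
provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import signal

from .trajectory import Keypoint, Trajectory, TrajectoryError

__all__ = [
    "DistanceSeries",
    "FilterConfig",
    "keypoint_distance",
    "build_distance_series",
    "lowpass_filter",
    "median_filter",
    "apply_filter",
]


@dataclass
class DistanceSeries:
    """Per-frame nose-mouth distances, possibly split into segments.

    ``segments`` is a list of half-open ``(start, stop)`` index ranges into
    ``values``; segment boundaries mark detection gaps too long to
    interpolate across.  Filters and the peak detector operate per segment.
    """

    values: np.ndarray
    frame_indices: np.ndarray
    fps: float
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.values.shape != self.frame_indices.shape:
            raise TrajectoryError("values and frame_indices must align")
        if not self.segments:
            self.segments = [(0, len(self.values))] if len(self.values) else []
        stops = [s for _, s in self.segments]
        starts = [s for s, _ in self.segments]
        if self.segments and (starts[0] != 0 or stops[-1] != len(self.values)
                              or any(a != b for a, b in zip(stops, starts[1:]))):
            raise TrajectoryError("segments must partition the index range")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return self.frame_indices / self.fps

    def with_values(self, values: np.ndarray) -> "DistanceSeries":
        return DistanceSeries(
            values=np.asarray(values, dtype=float),
            frame_indices=self.frame_indices.copy(),
            fps=self.fps,
            segments=list(self.segments),
        )


@dataclass(frozen=True)
class FilterConfig:
    """Denoising configuration.

    kind
        ``"lowpass"`` (zero-phase Butterworth), ``"median"`` (sliding
        window, shrinking at segment edges) or ``"none"``.
    cutoff_hz
        Low-pass corner frequency.  Chewing sits near 1.2-1.5 Hz at 30 fps
        (one jaw cycle is roughly 20 frames), so the default 3 Hz keeps the
        chewing band intact while rejecting detector jitter.
    order
        Butterworth order (applied forward and backward, so the effective
        attenuation is squared).
    window
        Median window length in frames; must be odd.
    """

    kind: Literal["lowpass", "median", "none"] = "lowpass"
    cutoff_hz: float = 3.0
    order: int = 4
    window: int = 5

    def validate(self, fps: float) -> None:
        if self.kind not in ("lowpass", "median", "none"):
            raise TrajectoryError(f"unknown filter kind {self.kind!r}")
        if self.kind == "lowpass":
            if not 0 < self.cutoff_hz < fps / 2:
                raise TrajectoryError(
                    f"cutoff_hz must lie in (0, fps/2)=(0, {fps / 2}), "
                    f"got {self.cutoff_hz}"
                )
            if self.order < 1:
                raise TrajectoryError(f"order must be >= 1, got {self.order}")
        if self.kind == "median":
            if self.window < 1 or self.window % 2 == 0:
                raise TrajectoryError(
                    f"median window must be odd and >= 1, got {self.window}"
                )


def keypoint_distance(a: Keypoint, b: Keypoint) -> float:
    """Euclidean pixel distance between two keypoints."""
    if a is None or b is None:
        raise TrajectoryError("keypoint_distance requires two present keypoints")
    return float(np.hypot(a.x - b.x, a.y - b.y))


def build_distance_series(traj: Trajectory, max_gap_frames: int = 10) -> DistanceSeries:
    """Build the rumination motion curve from a trajectory.

    Runs of at most ``max_gap_frames`` consecutive undetected frames are
    filled by linear interpolation of the distance; longer runs split the
    series into separate segments.  Leading/trailing undetected frames are
    dropped (there is nothing to interpolate from).
    """
    detected = [(f.frame_index, keypoint_distance(f.nose, f.mouth))
                for f in traj.frames if f.detected]
    if not detected:
        raise TrajectoryError("trajectory has no detected frames")

    frames = np.array([fi for fi, _ in detected], dtype=int)
    dists = np.array([d for _, d in detected], dtype=float)

    out_frames: list[int] = [int(frames[0])]
    out_values: list[float] = [float(dists[0])]
    seg_starts = [0]
    for k in range(1, len(frames)):
        gap = int(frames[k] - frames[k - 1]) - 1  # undetected frames in between
        if gap == 0:
            pass
        elif gap <= max_gap_frames:
            # linear fill at the missing integer frame indices
            for fi in range(int(frames[k - 1]) + 1, int(frames[k])):
                t = (fi - frames[k - 1]) / (frames[k] - frames[k - 1])
                out_frames.append(fi)
                out_values.append(float(dists[k - 1] + t * (dists[k] - dists[k - 1])))
        else:
            seg_starts.append(len(out_frames))
        out_frames.append(int(frames[k]))
        out_values.append(float(dists[k]))

    bounds = seg_starts + [len(out_frames)]
    segments = [(bounds[i], bounds[i + 1]) for i in range(len(seg_starts))]
    return DistanceSeries(
        values=np.array(out_values),
        frame_indices=np.array(out_frames),
        fps=traj.fps,
        segments=segments,
    )


def _min_lowpass_len(order: int) -> int:
    # filtfilt's default padlen for a transfer-function filter of this order
    return 3 * (order + 1) + 1


def lowpass_filter(series: DistanceSeries, cfg: FilterConfig) -> DistanceSeries:
    """Zero-phase Butterworth low-pass, applied independently per segment.

    Forward-backward filtering leaves peak positions unshifted.  Segments
    shorter than the filter's padding requirement are an error (the caller
    should either drop them or widen the gap policy).
    """
    if cfg.kind != "lowpass":
        raise TrajectoryError(f"lowpass_filter needs kind='lowpass', got {cfg.kind!r}")
    cfg.validate(series.fps)
    min_len = _min_lowpass_len(cfg.order)
    too_short = [seg for seg in series.segments if seg[1] - seg[0] < min_len]
    if too_short:
        raise TrajectoryError(
            f"segments {too_short} are shorter than {min_len} samples required "
            f"by the order-{cfg.order} zero-phase filter"
        )
    b, a = signal.butter(cfg.order, cfg.cutoff_hz, btype="low", fs=series.fps)
    out = series.values.copy()
    for lo, hi in series.segments:
        out[lo:hi] = signal.filtfilt(b, a, series.values[lo:hi])
    return series.with_values(out)


def median_filter(series: DistanceSeries, cfg: FilterConfig) -> DistanceSeries:
    """Sliding-window median per segment; the window shrinks at edges."""
    if cfg.kind != "median":
        raise TrajectoryError(f"median_filter needs kind='median', got {cfg.kind!r}")
    cfg.validate(series.fps)
    out = series.values.copy()
    for lo, hi in series.segments:
        seg = pd.Series(series.values[lo:hi])
        out[lo:hi] = seg.rolling(cfg.window, center=True, min_periods=1).median().to_numpy()
    return series.with_values(out)


def apply_filter(series: DistanceSeries, cfg: FilterConfig) -> DistanceSeries:
    """Dispatch on ``cfg.kind``; ``"none"`` returns the input unchanged."""
    if cfg.kind == "lowpass":
        return lowpass_filter(series, cfg)
    if cfg.kind == "median":
        return median_filter(series, cfg)
    if cfg.kind == "none":
        return series
    raise TrajectoryError(f"unknown filter kind {cfg.kind!r}")
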