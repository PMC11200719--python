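"""Session indicators: chew count, rumination duration, chewing frequency.

Rumination sessions are summarised by three indicators.  Duration is
measured between chew events: consecutive chews whose gap is at most the
rest threshold (3 s by default — gaps *exceeding* three seconds are rest,
a gap of exactly 3 s still counts as rumination) belong to one bout, and a
bout contributes last-minus-first chew time.  Excluded rest accumulates
the gaps that were too long.  Chewing frequency is the ratio of chew count
to rumination duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detector import DetectorConfig, PeakSet, count_chews
from .motion import FilterConfig
from .trajectory import Trajectory, TrajectoryError

__all__ = [
    "Bout",
    "SessionSummary",
    "rumination_duration",
    "chewing_frequency",
    "summarize_session",
    "rolling_chew_frequency",
]


@dataclass(frozen=True)
class Bout:
    """One uninterrupted run of chewing."""

    start_s: float
    end_s: float
    chew_count: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionSummary:
    chew_count: int
    rumination_duration_s: float
    chew_frequency_hz: float  # NaN when duration is zero
    bouts: list[Bout] = field(default_factory=list)
    excluded_rest_s: float = 0.0
    threshold_used: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "chew_count": self.chew_count,
            "rumination_duration_s": self.rumination_duration_s,
            "chew_frequency_hz": self.chew_frequency_hz,
            "bouts": [
                {"start_s": b.start_s, "end_s": b.end_s, "chew_count": b.chew_count}
                for b in self.bouts
            ],
            "excluded_rest_s": self.excluded_rest_s,
            "threshold_used": self.threshold_used,
        }


def rumination_duration(
    chew_times: Sequence[float], rest_gap_s: float = 3.0
) -> tuple[float, list[Bout], float]:
    """Segment chew times into bouts and total the within-bout time.

    Returns ``(duration_s, bouts, excluded_rest_s)``.  The identity
    ``duration_s + excluded_rest_s == last - first`` chew time holds
    exactly.  A single chew forms a zero-length bout.
    """
    if rest_gap_s <= 0:
        raise TrajectoryError("rest_gap_s must be positive")
    times = np.asarray(chew_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise TrajectoryError("chew_times must be sorted ascending")
    if len(times) == 0:
        return 0.0, [], 0.0

    bouts: list[Bout] = []
    excluded = 0.0
    start = 0
    for k in range(1, len(times)):
        gap = times[k] - times[k - 1]
        if gap > rest_gap_s:
            bouts.append(Bout(float(times[start]), float(times[k - 1]), k - start))
            excluded += float(gap)
            start = k
    bouts.append(Bout(float(times[start]), float(times[-1]), len(times) - start))
    duration = float(sum(b.duration_s for b in bouts))
    return duration, bouts, excluded


def chewing_frequency(chew_count: int, duration_s: float) -> float:
    """Chews per second; NaN marks the undefined zero-duration case."""
    if chew_count < 0 or duration_s < 0:
        raise TrajectoryError("chew_count and duration_s must be non-negative")
    if duration_s == 0:
        return float("nan")
    return chew_count / duration_s


def summarize_session(
    traj: Trajectory,
    filter_cfg: FilterConfig = FilterConfig(),
    det_cfg: DetectorConfig = DetectorConfig(),
    rest_gap_s: float = 3.0,
    max_gap_frames: int = 10,
) -> SessionSummary:
    """Run the full pipeline and report the three session indicators."""
    peaks = count_chews(traj, filter_cfg, det_cfg, max_gap_frames=max_gap_frames)
    times = peaks.peak_times_s
    duration, bouts, excluded = rumination_duration(times, rest_gap_s)
    return SessionSummary(
        chew_count=peaks.count,
        rumination_duration_s=duration,
        chew_frequency_hz=chewing_frequency(peaks.count, duration),
        bouts=bouts,
        excluded_rest_s=excluded,
        threshold_used=peaks.threshold_used,
    )


def rolling_chew_frequency(
    chew_times: Sequence[float],
    window_s: float = 10.0,
    step_s: float = 1.0,
    span: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Real-time chewing frequency as a sliding-window series.

    At each evaluation time ``t`` the frequency is the number of chews in
    ``(t - window_s, t]`` divided by ``window_s``.  Returns ``(times,
    frequencies_hz)``.
    """
    if window_s <= 0 or step_s <= 0:
        raise TrajectoryError("window_s and step_s must be positive")
    times = np.asarray(chew_times, dtype=float)
    if span is None:
        if len(times) == 0:
            return np.array([]), np.array([])
        span = (float(times[0]), float(times[-1]))
    grid = np.arange(span[0], span[1] + step_s / 2, step_s)
    counts = np.array(
        [np.sum((times > t - window_s) & (times <= t)) for t in grid], dtype=float
    )
    return grid, counts / window_s
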