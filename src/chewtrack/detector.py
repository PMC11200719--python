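"""Chew counting by multi-condition threshold peak detection.

A chew is accepted at index ``i`` of the (filtered) distance series when
all of the following hold, scanning left to right within each segment:

* ``d[i] - d[i-1] > 0`` and ``d[i] - d[i+1] > 0`` (strict local maximum);
* ``d[i] > threshold`` — by default the *median* of the whole series, a
  dynamic threshold chosen because rest-period wobble stays below the
  median while genuine chew crests rise above it, and the median is robust
  to outliers;
* the index gap to the previously accepted chew is strictly greater than
  ``min_spacing_frames`` (default 20 frames at 30 fps, roughly one jaw
  cycle), which suppresses double counts from head shaking.

Endpoints are never peaks, the first acceptance in a segment carries no
spacing constraint, and the spacing counter never crosses a segment
boundary (segments are separated by detection gaps with no signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .motion import DistanceSeries, FilterConfig, apply_filter, build_distance_series
from .trajectory import Trajectory, TrajectoryError

__all__ = [
    "DetectorConfig",
    "PeakSet",
    "dynamic_threshold",
    "detect_chew_peaks",
    "count_chews",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-detector parameters.

    ``min_spacing_frames`` is defined at 30 fps and rescaled by ``fps/30``
    when the series runs at a different rate.  ``threshold_mode``:

    * ``"median"`` — median of the full (per-segment concatenated) series;
    * ``"fixed"`` — a user-supplied pixel threshold;
    * ``"rolling_median"`` — a centred rolling median of width
      ``rolling_window_s``, for long recordings whose camera distance (and
      hence pixel scale) drifts.

    ``threshold_on_raw`` computes the median threshold from the unfiltered
    series instead of the filtered one the detector scans.
    ``plateau_policy="midpoint"`` treats a maximal flat run flanked by
    ascent and descent as one peak at its centre; the default ``"strict"``
    follows the strict inequalities literally, so plateaus are not peaks.
    """

    min_spacing_frames: int = 20
    threshold_mode: Literal["median", "fixed", "rolling_median"] = "median"
    fixed_threshold: Optional[float] = None
    rolling_window_s: float = 10.0
    threshold_on_raw: bool = False
    plateau_policy: Literal["strict", "midpoint"] = "strict"

    def validate(self) -> None:
        if self.min_spacing_frames < 0:
            raise TrajectoryError("min_spacing_frames must be >= 0")
        if self.threshold_mode == "fixed":
            if self.fixed_threshold is None or self.fixed_threshold < 0:
                raise TrajectoryError(
                    "threshold_mode='fixed' requires fixed_threshold >= 0"
                )
        if self.threshold_mode == "rolling_median" and self.rolling_window_s <= 0:
            raise TrajectoryError("rolling_window_s must be positive")
        if self.threshold_mode not in ("median", "fixed", "rolling_median"):
            raise TrajectoryError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.plateau_policy not in ("strict", "midpoint"):
            raise TrajectoryError(f"unknown plateau_policy {self.plateau_policy!r}")

    def effective_spacing(self, fps: float) -> int:
        """Spacing in frames at the series' rate (the default is tied to 30 fps)."""
        return int(round(self.min_spacing_frames * fps / 30.0))


@dataclass
class PeakSet:
    """Accepted chew peaks plus bookkeeping about what was rejected."""

    peak_indices: np.ndarray  # frame indices of accepted chews
    threshold_used: float
    rejected: dict[str, int] = field(
        default_factory=lambda: {"below_threshold": 0, "too_close": 0,
                                 "not_local_max": 0}
    )
    fps: float = 30.0

    @property
    def count(self) -> int:
        return len(self.peak_indices)

    @property
    def peak_times_s(self) -> np.ndarray:
        return np.asarray(self.peak_indices, dtype=float) / self.fps


def dynamic_threshold(series: DistanceSeries) -> float:
    """Median of all distances — the dynamic threshold.

    For even lengths this is the midpoint of the two central order
    statistics.
    """
    if len(series) == 0:
        raise TrajectoryError("cannot take the median of an empty series")
    return float(np.median(series.values))


def _threshold_array(series: DistanceSeries, cfg: DetectorConfig) -> np.ndarray:
    n = len(series)
    if cfg.threshold_mode == "fixed":
        return np.full(n, float(cfg.fixed_threshold))
    if cfg.threshold_mode == "median":
        return np.full(n, dynamic_threshold(series))
    # rolling median, window centred, computed per segment
    window = max(1, int(round(cfg.rolling_window_s * series.fps)))
    out = np.empty(n)
    for lo, hi in series.segments:
        seg = pd.Series(series.values[lo:hi])
        out[lo:hi] = seg.rolling(window, center=True, min_periods=1).median().to_numpy()
    return out


def _plateau_candidates(d: np.ndarray, lo: int, hi: int) -> list[int]:
    """Midpoints of maximal flat runs flanked by strict ascent and descent."""
    cands = []
    i = lo + 1
    while i < hi - 1:
        j = i
        while j + 1 < hi and d[j + 1] == d[i]:
            j += 1
        # run d[i..j]; needs strict rise before and strict fall after
        if j < hi - 1 and d[i] - d[i - 1] > 0 and d[j] - d[j + 1] > 0:
            cands.append((i + j) // 2)
        i = j + 1
    return cands


def detect_chew_peaks(
    series: DistanceSeries,
    cfg: DetectorConfig = DetectorConfig(),
    threshold_override: Optional[float] = None,
) -> PeakSet:
    """Scan the series and return accepted chew peaks.

    Acceptance is greedy left to right: once a peak is accepted, any later
    candidate within the spacing window is rejected even if taller.  The
    ``rejected`` tally records local maxima that failed the threshold
    (``below_threshold``), ones that failed the spacing rule
    (``too_close``), and above-threshold samples that were not local
    maxima (``not_local_max``).
    """
    cfg.validate()
    d = series.values
    if threshold_override is not None:
        thr = np.full(len(d), float(threshold_override))
    else:
        thr = _threshold_array(series, cfg)
    spacing = cfg.effective_spacing(series.fps)

    accepted: list[int] = []
    rejected = {"below_threshold": 0, "too_close": 0, "not_local_max": 0}
    for lo, hi in series.segments:
        if cfg.plateau_policy == "midpoint":
            candidates = _plateau_candidates(d, lo, hi)
            cand_set = set(candidates)
        else:
            candidates = [i for i in range(lo + 1, hi - 1)
                          if d[i] - d[i - 1] > 0 and d[i] - d[i + 1] > 0]
            cand_set = set(candidates)
        rejected["not_local_max"] += int(
            sum(1 for i in range(lo + 1, hi - 1)
                if d[i] > thr[i] and i not in cand_set)
        )
        last: Optional[int] = None
        for i in candidates:
            if not d[i] > thr[i]:
                rejected["below_threshold"] += 1
                continue
            if last is not None and not (i - last > spacing):
                rejected["too_close"] += 1
                continue
            accepted.append(i)
            last = i

    peak_frames = series.frame_indices[np.array(accepted, dtype=int)] \
        if accepted else np.array([], dtype=int)
    scalar_thr = float(np.median(thr)) if len(thr) else float("nan")
    return PeakSet(peak_indices=peak_frames, threshold_used=scalar_thr,
                   rejected=rejected, fps=series.fps)


def count_chews(
    traj: Trajectory,
    filter_cfg: FilterConfig = FilterConfig(),
    det_cfg: DetectorConfig = DetectorConfig(),
    max_gap_frames: int = 10,
) -> PeakSet:
    """Full pipeline: distance series -> filter -> dynamic threshold -> peaks."""
    raw = build_distance_series(traj, max_gap_frames=max_gap_frames)
    filtered = apply_filter(raw, filter_cfg)
    override = None
    if det_cfg.threshold_on_raw and det_cfg.threshold_mode == "median":
        override = dynamic_threshold(raw)
    return detect_chew_peaks(filtered, det_cfg, threshold_override=override)
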