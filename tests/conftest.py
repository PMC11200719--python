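"""Shared fixtures: small trajectory builders and bundled data paths."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from chewtrack import DistanceSeries, FramePose, Keypoint, Trajectory


@pytest.fixture
def make_trajectory():
    """Factory: build a Trajectory from a sequence of distances.

    The nose sits at a fixed anchor and the mouth directly below it at the
    requested distance; None entries become undetected frames.
    """

    def _make(distances, fps=30.0, anchor=(100.0, 80.0)):
        frames = []
        for i, d in enumerate(distances):
            if d is None:
                frames.append(FramePose(frame_index=i, time_s=i / fps))
            else:
                frames.append(
                    FramePose(
                        frame_index=i,
                        time_s=i / fps,
                        nose=Keypoint(anchor[0], anchor[1]),
                        mouth=Keypoint(anchor[0], anchor[1] + float(d)),
                    )
                )
        return Trajectory(frames=frames, fps=fps)

    return _make


@pytest.fixture
def make_series():
    """Factory: wrap raw values in a DistanceSeries (single segment)."""

    def _make(values, fps=30.0, segments=None):
        values = np.asarray(values, dtype=float)
        return DistanceSeries(
            values=values,
            frame_indices=np.arange(len(values)),
            fps=fps,
            segments=segments or [],
        )

    return _make


@pytest.fixture
def manual_counts_path() -> Path:
    import chewtrack

    return Path(chewtrack.__file__).parent / "data" / "manual_chew_counts.csv"
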