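"""Assemble per-frame detections into a path and measure distance.

The path metric is the summed Euclidean distance between the contour
centroids of consecutive detected frames,

    d = Σ sqrt((x_i − x_{i+1})² + (y_i − y_{i+1})²) / pixels_per_mm.

Frames where detection failed contribute no position.  When a gap of failed
frames separates two detections, the default policy bridges the gap with a
single straight-line step (a lower bound on the true distance travelled);
``gap_policy="skip"`` excludes bridging steps instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detection import (DEFAULT_MIN_AREA, FrameDetection, HsvRange,
                        detect_in_frame)
from .video_io import CropRect, IDENTITY_SCALE, ScaleCalibration, VideoSource

__all__ = [
    "TrackedPath",
    "PathSummary",
    "step_distance",
    "track",
    "track_multi",
    "total_distance",
    "step_distances",
    "summarise",
]

log = logging.getLogger(__name__)

GAP_POLICIES = ("bridge", "skip")


@dataclass(frozen=True)
class TrackedPath:
    """One video × one colour threshold: a detection per frame, in order."""

    detections: tuple[FrameDetection, ...]
    fps: float
    scale: ScaleCalibration
    video_id: str
    threshold: HsvRange | None = None

    def __post_init__(self) -> None:
        idx = [d.frame_index for d in self.detections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("detections must have strictly increasing frame_index")

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    @property
    def n_detected(self) -> int:
        return sum(d.found for d in self.detections)

    def found_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(frame indices, (n, 2) centroid array) over found frames only."""
        found = [d for d in self.detections if d.found]
        if not found:
            return np.empty(0, dtype=int), np.empty((0, 2))
        idx = np.array([d.frame_index for d in found])
        xy = np.array([[d.centroid_x, d.centroid_y] for d in found])
        return idx, xy

    def translated(self, dx: float, dy: float) -> "TrackedPath":
        """Shift every position by (dx, dy); distances are unaffected."""
        moved = tuple(
            replace(d, centroid_x=d.centroid_x + dx, centroid_y=d.centroid_y + dy,
                    rect_cx=d.rect_cx + dx, rect_cy=d.rect_cy + dy) if d.found else d
            for d in self.detections)
        return replace(self, detections=moved)


@dataclass(frozen=True)
class PathSummary:
    video_id: str
    n_frames: int
    total_distance_mm: float
    scaling_factor: float  # pixels per mm
    n_detected: int


def step_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean distance between two pixel positions."""
    return math.hypot(p1[0] - p2[0], p1[1] - p2[1])


def _check_gap_policy(gap_policy: str) -> None:
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"gap_policy must be one of {GAP_POLICIES}, got {gap_policy!r}")


def step_distances(path: TrackedPath, gap_policy: str = "bridge"
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-step distances in mm between consecutive found frames.

    Returns ``(distances_mm, start_frames, end_frames)``: step ``i`` runs
    from frame ``start_frames[i]`` to ``end_frames[i]``.  Under ``"bridge"``
    a step spanning a not-found gap is included like any other; under
    ``"skip"`` only steps between adjacent frames survive.
    """
    _check_gap_policy(gap_policy)
    idx, xy = path.found_positions()
    if idx.size < 2:
        return np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int)
    d_px = np.hypot(*(np.diff(xy, axis=0).T))
    starts, ends = idx[:-1], idx[1:]
    if gap_policy == "skip":
        adjacent = np.diff(idx) == 1
        d_px, starts, ends = d_px[adjacent], starts[adjacent], ends[adjacent]
    return d_px / path.scale.pixels_per_mm, starts, ends


def total_distance(path: TrackedPath, gap_policy: str = "bridge") -> float:
    """Total distance travelled in mm (pixels when uncalibrated)."""
    d, _, _ = step_distances(path, gap_policy)
    return float(d.sum())


def track(video: VideoSource, rng: HsvRange,
          crop: CropRect | None = None,
          scale: ScaleCalibration = IDENTITY_SCALE,
          min_area: float = DEFAULT_MIN_AREA) -> TrackedPath:
    """Run detection on every frame of ``video``.

    Deterministic: identical input and parameters give identical output.
    A video with no detections at all is returned (with a warning), not an
    error — the path CSV still documents the run.
    """
    if crop is not None:
        crop.validate_against(video.width, video.height)
    detections = tuple(
        detect_in_frame(frame, rng, crop, min_area).with_index(i)
        for i, frame in enumerate(video)
    )
    path = TrackedPath(detections=detections, fps=video.fps, scale=scale,
                       video_id=video.path.name, threshold=rng)
    if path.n_detected == 0:
        log.warning("no frame of %s matched the threshold window", video.path)
    return path


def track_multi(video: VideoSource, ranges: Mapping[str, HsvRange],
                crop: CropRect | None = None,
                scale: ScaleCalibration = IDENTITY_SCALE,
                min_area: float = DEFAULT_MIN_AREA) -> dict[str, TrackedPath]:
    """Independent single-target runs over the same frame stream, one per
    named colour window (e.g. ``{"right_paw_red": ..., "left_paw_blue": ...}``)."""
    names = list(ranges)
    if not names:
        raise ValueError("at least one named HSV range is required")
    if len(set(names)) != len(names):
        raise ValueError("range names must be unique")
    out = {}
    for name, rng in ranges.items():
        p = track(video, rng, crop=crop, scale=scale, min_area=min_area)
        out[name] = replace(p, video_id=f"{video.path.name}:{name}")
    return out


def summarise(path: TrackedPath, gap_policy: str = "bridge") -> PathSummary:
    return PathSummary(
        video_id=path.video_id,
        n_frames=path.n_frames,
        total_distance_mm=total_distance(path, gap_policy),
        scaling_factor=path.scale.pixels_per_mm,
        n_detected=path.n_detected,
    )
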