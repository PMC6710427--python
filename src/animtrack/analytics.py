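"""Kinematic analytics on tracked paths.

Everything here operates on a :class:`~animtrack.tracking.TrackedPath`
(re-loadable from a path CSV), decoupled from detection, so analyses can be
re-run and tuned without re-decoding video.

Instantaneous velocity follows the distance-per-short-window convention:
the path is tiled into windows of ``window_frames`` consecutive detected
frames and each window's travelled distance is divided by its duration.
At 30 fps the default 10-frame window corresponds to 333 ms.

The larval stride/turn analysis treats the larger dimension of the per-frame
minimum rotated rectangle as the larva's body length.  Peristaltic crawling
shows up as an oscillation of that length; one stride is one extension →
contraction cycle, extracted as a (local maximum, following local minimum)
pair of the smoothed length trace.  A turning larva curls, which lowers its
length:width aspect ratio, so frames whose aspect ratio drops well below the
animal's typical elongation are classified as turns and host no strides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .tracking import TrackedPath, step_distances, total_distance

__all__ = [
    "VelocitySeries",
    "RegionSpec",
    "DistanceBins",
    "StrideEvent",
    "StrideProfile",
    "NoDetectionsError",
    "instantaneous_velocity",
    "bin_distances",
    "region_occupancy",
    "segment_cv",
    "normalise_path",
    "stride_analysis",
]


class NoDetectionsError(ValueError):
    """An analysis that needs detected frames got a path with none."""


@dataclass(frozen=True)
class VelocitySeries:
    """Velocity per window of consecutive detected frames.

    ``frame_index[i]`` is the first frame of window ``i``; each window spans
    ``window_frames`` steps (frames t .. t+window_frames), and windows tile
    each unbroken run of detections without overlap.
    """

    frame_index: np.ndarray
    velocity_mm_per_s: np.ndarray
    window_frames: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame_index": self.frame_index,
                             "velocity_mm_per_s": self.velocity_mm_per_s})


@dataclass(frozen=True)
class RegionSpec:
    """Named axis-aligned rectangle in cropped-frame pixel coordinates."""

    x: float
    y: float
    w: float
    h: float
    name: str = "region"

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"region {self.name!r} must have positive size")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary counts as inside."""
        return ((x >= self.x) & (x <= self.x + self.w)
                & (y >= self.y) & (y <= self.y + self.h))


def instantaneous_velocity(path: TrackedPath,
                           window_frames: int = 10) -> VelocitySeries:
    """Distance travelled per ``window_frames``-frame window, over time.

    Windows containing any not-found frame are omitted rather than
    interpolated.  A window longer than the longest detection run yields an
    empty series.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    if path.fps <= 0:
        raise ValueError("path has no usable frame rate")
    idx, xy = path.found_positions()
    starts: list[int] = []
    vels: list[float] = []
    window_s = window_frames / path.fps
    i = 0
    while i < idx.size:
        # maximal run of consecutive frame indices starting at i
        j = i
        while j + 1 < idx.size and idx[j + 1] == idx[j] + 1:
            j += 1
        s = i
        while s + window_frames <= j:
            seg = xy[s:s + window_frames + 1]
            dist_px = np.hypot(*np.diff(seg, axis=0).T).sum()
            starts.append(int(idx[s]))
            vels.append(dist_px / path.scale.pixels_per_mm / window_s)
            s += window_frames
        i = j + 1
    return VelocitySeries(np.array(starts, dtype=int), np.array(vels),
                          window_frames)


@dataclass(frozen=True)
class DistanceBins:
    """Histogram of per-step distances plus per-time-bin travel totals."""

    bin_width_mm: float
    steps: pd.DataFrame      # bin_left_mm, bin_right_mm, n_steps, distance_mm
    time_bins: pd.DataFrame  # t_start_s, t_end_s, distance_mm

    @property
    def total_mm(self) -> float:
        return float(self.steps["distance_mm"].sum())


def bin_distances(path: TrackedPath, bin_width_mm: float,
                  gap_policy: str = "bridge",
                  time_bin_s: float = 60.0) -> DistanceBins:
    """Bin step distances into half-open bins [k·w, (k+1)·w).

    Conservation holds by construction: the summed per-bin distance equals
    the path's total distance under the same gap policy.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be positive")
    if time_bin_s <= 0:
        raise ValueError("time_bin_s must be positive")
    d, _, ends = step_distances(path, gap_policy)
    if d.size:
        k = np.floor(d / bin_width_mm).astype(int)
        steps = (pd.DataFrame({"bin": k, "distance_mm": d})
                 .groupby("bin").agg(n_steps=("bin", "size"),
                                     distance_mm=("distance_mm", "sum"))
                 .reset_index())
        t = np.floor(ends / path.fps / time_bin_s).astype(int)
        tb = (pd.DataFrame({"t": t, "distance_mm": d})
              .groupby("t")["distance_mm"].sum().reset_index())
    else:
        steps = pd.DataFrame({"bin": [], "n_steps": [], "distance_mm": []})
        tb = pd.DataFrame({"t": [], "distance_mm": []})
    steps["bin_left_mm"] = steps["bin"] * bin_width_mm
    steps["bin_right_mm"] = (steps["bin"] + 1) * bin_width_mm
    steps = steps[["bin_left_mm", "bin_right_mm", "n_steps", "distance_mm"]]
    tb["t_start_s"] = tb["t"] * time_bin_s
    tb["t_end_s"] = (tb["t"] + 1) * time_bin_s
    tb = tb[["t_start_s", "t_end_s", "distance_mm"]]
    return DistanceBins(bin_width_mm=bin_width_mm, steps=steps, time_bins=tb)


def region_occupancy(path: TrackedPath, region: RegionSpec) -> float:
    """Fraction of detected frames whose centroid lies in ``region``
    (boundary inclusive).  Undefined — raises — when nothing was detected."""
    _, xy = path.found_positions()
    if xy.shape[0] == 0:
        raise NoDetectionsError(
            f"occupancy of {region.name!r} is undefined: no detected frames")
    return float(region.contains(xy[:, 0], xy[:, 1]).mean())


def segment_cv(path: TrackedPath, segment_seconds: list[float],
               gap_policy: str = "bridge") -> pd.DataFrame:
    """Coefficient of variation of per-segment travel distances.

    The path is split into consecutive non-overlapping segments of each
    requested duration (complete segments only), each treated as if it were
    its own recording: a step counts toward a segment only when both its
    endpoints lie inside that segment, so boundary-crossing steps are
    dropped.  CV% = sample sd / mean of the segment distances × 100.
    Durations yielding fewer than two complete segments are skipped with a
    warning.  Used to pick the shortest recording that still estimates a
    session's travel rate reliably.
    """
    d, starts, ends = step_distances(path, gap_policy)
    n_frames = path.n_frames
    rows = []
    for dur in segment_seconds:
        seg_frames = int(round(dur * path.fps))
        n_seg = n_frames // seg_frames if seg_frames > 0 else 0
        if n_seg < 2:
            warnings.warn(f"segment duration {dur}s gives {n_seg} complete "
                          f"segment(s); skipped", stacklevel=2)
            continue
        seg_of_step = starts // seg_frames
        keep = (seg_of_step == ends // seg_frames) & (ends < n_seg * seg_frames)
        totals = np.bincount(seg_of_step[keep], weights=d[keep], minlength=n_seg)
        mean = totals.mean()
        cv = math.nan if mean == 0 else float(totals.std(ddof=1) / mean * 100.0)
        rows.append({"duration_s": dur, "n_segments": n_seg, "cv_percent": cv})
    return pd.DataFrame(rows, columns=["duration_s", "n_segments", "cv_percent"])


def normalise_path(path: TrackedPath) -> TrackedPath:
    """Translate the path so its first detected centroid is (0, 0); used to
    overlay paths from different recordings on a common origin."""
    _, xy = path.found_positions()
    if xy.shape[0] == 0:
        raise NoDetectionsError("cannot normalise a path with no detections")
    return path.translated(-xy[0, 0], -xy[0, 1])


@dataclass(frozen=True)
class StrideEvent:
    peak_frame: int
    trough_frame: int
    amplitude_px: float


@dataclass(frozen=True)
class StrideProfile:
    """Per-frame larval shape series plus extracted stride events."""

    frame_index: np.ndarray
    length_px: np.ndarray
    width_px: np.ndarray
    aspect_ratio: np.ndarray
    smoothed_length_px: np.ndarray
    stride_events: tuple[StrideEvent, ...]
    mean_amplitude_mm: float  # NaN when no stride events
    turn_frames: tuple[int, ...]
    smooth_window: int
    ratio_turn_threshold: float
    min_prominence_px: float

    @property
    def n_strides(self) -> int:
        return len(self.stride_events)

    def to_frame(self) -> pd.DataFrame:
        turn = np.isin(self.frame_index, self.turn_frames)
        return pd.DataFrame({
            "frame_index": self.frame_index,
            "length_px": self.length_px,
            "width_px": self.width_px,
            "aspect_ratio": self.aspect_ratio,
            "smoothed_length_px": self.smoothed_length_px,
            "turn": turn.astype(int),
        })


def _centred_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with truncated windows at the edges."""
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def stride_analysis(path: TrackedPath, smooth_window: int = 5,
                    ratio_turn_threshold: float = 0.6,
                    min_prominence_px: float = 2.0) -> StrideProfile:
    """Extract stride (contraction) events and turn frames from a larva path.

    Per detected frame the body length is the minimum-rotated-rectangle
    length (``rect_l``) and the width its shorter side.  The length trace is
    smoothed with a centred ``smooth_window``-frame moving average; local
    maxima/minima with prominence ≥ ``min_prominence_px`` are paired into
    (peak, following trough) stride events, each extremum refined to the raw
    trace's extremum within half a smoothing window.  A frame is a turn when
    its aspect ratio falls below ``ratio_turn_threshold`` × the video-median
    aspect ratio; events overlapping turn frames are discarded.

    Amplitude is peak-to-trough on the raw length trace, reported in mm.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    found = [d for d in path.detections if d.found]
    if not found:
        raise NoDetectionsError("stride analysis needs detected frames")
    frames = np.array([d.frame_index for d in found])
    length = np.array([d.rect_l for d in found])
    width = np.array([d.rect_w for d in found])
    with np.errstate(divide="ignore", invalid="ignore"):
        aspect = np.where(width > 0, length / np.maximum(width, 1e-12), np.nan)
    smoothed = _centred_moving_average(length, smooth_window)

    med = np.nanmedian(aspect)
    turn_mask = aspect < ratio_turn_threshold * med
    turn_positions = np.nonzero(turn_mask)[0]
    turn_frames = tuple(int(f) for f in frames[turn_positions])

    # pad with a below-minimum sentinel so a genuine extremum near the trace
    # edge keeps its full prominence (truncated bases would deflate it);
    # noise wiggles are still rejected by their interior-side prominence
    lo = smoothed.min() - 1.0
    hi = smoothed.max() + 1.0
    peaks = find_peaks(np.r_[lo, smoothed, lo],
                       prominence=min_prominence_px)[0] - 1
    troughs = find_peaks(np.r_[-hi, -smoothed, -hi],
                         prominence=min_prominence_px)[0] - 1
    half = smooth_window // 2

    def refine(pos: int, maximum: bool) -> int:
        lo, hi = max(0, pos - half), min(length.size, pos + half + 1)
        window = length[lo:hi]
        off = int(np.argmax(window) if maximum else np.argmin(window))
        return lo + off

    # alternate through the merged extremum sequence: each trough closes the
    # most recent unclosed peak
    extrema = sorted([(p, "peak") for p in peaks] + [(t, "trough") for t in troughs])
    events: list[StrideEvent] = []
    open_peak: int | None = None
    turn_set = set(turn_positions.tolist())
    for pos, kind in extrema:
        if kind == "peak":
            open_peak = pos
        elif open_peak is not None:
            p = refine(open_peak, maximum=True)
            t = refine(pos, maximum=False)
            open_peak = None
            if any(q in turn_set for q in range(p, t + 1)):
                continue
            amp = float(length[p] - length[t])
            if amp <= 0:
                continue
            events.append(StrideEvent(int(frames[p]), int(frames[t]), amp))
    amps = [e.amplitude_px for e in events]
    mean_amp_mm = (float(np.mean(amps)) / path.scale.pixels_per_mm
                   if amps else math.nan)
    return StrideProfile(
        frame_index=frames, length_px=length, width_px=width,
        aspect_ratio=aspect, smoothed_length_px=smoothed,
        stride_events=tuple(events), mean_amplitude_mm=mean_amp_mm,
        turn_frames=turn_frames, smooth_window=smooth_window,
        ratio_turn_threshold=ratio_turn_threshold,
        min_prominence_px=min_prominence_px,
    )
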