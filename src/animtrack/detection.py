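"""Per-frame object detection.

The detection chain mirrors the classic colour-tracking recipe: convert the
frame to HSV, keep pixels inside a user-set threshold window, find connected
objects in the resulting binary mask, and record the largest one — its
area-weighted centroid and its minimum rotated rectangle, whose longer side
is taken as the animal's length and shorter side as its width.

Hue is in degrees [0, 360); a window with ``h_low > h_high`` wraps through 0°,
which is how red targets (the common tail-mark / housing colour) are selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops

from .video_io import CropRect, crop_frame

__all__ = [
    "HsvRange",
    "FrameDetection",
    "threshold_frame",
    "find_largest_object",
    "detect_in_frame",
    "DEFAULT_MIN_AREA",
]

#: Reject connected components smaller than this many px²; suppresses
#: salt noise that would otherwise win on frames where the animal is absent.
DEFAULT_MIN_AREA = 20.0


@dataclass(frozen=True)
class HsvRange:
    """A colour threshold window in HSV space, bounds inclusive.

    ``h_low``/``h_high`` in degrees [0, 360]; ``h_low > h_high`` denotes a
    wrapped hue interval passing through 0° (red).  Saturation and value in
    [0, 1].
    """

    h_low: float
    h_high: float
    s_low: float
    s_high: float
    v_low: float
    v_high: float

    def __post_init__(self) -> None:
        for name in ("h_low", "h_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 360.0:
                raise ValueError(f"{name}={v} outside [0, 360]")
        for name in ("s_low", "s_high", "v_low", "v_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.s_low > self.s_high:
            raise ValueError(f"s_low {self.s_low} > s_high {self.s_high}")
        if self.v_low > self.v_high:
            raise ValueError(f"v_low {self.v_low} > v_high {self.v_high}")

    @property
    def hue_wraps(self) -> bool:
        return self.h_low > self.h_high

    def hue_mask(self, hue_deg: np.ndarray) -> np.ndarray:
        if self.hue_wraps:
            return (hue_deg >= self.h_low) | (hue_deg <= self.h_high)
        return (hue_deg >= self.h_low) & (hue_deg <= self.h_high)


@dataclass(frozen=True)
class FrameDetection:
    """What was found (or not) in one frame.

    Geometry fields are NaN when ``found`` is False; ``rect_l >= rect_w``
    always (length is the larger dimension of the minimum rotated rectangle).
    ``rect_angle`` is the orientation of the length axis in degrees, [0, 180).
    """

    frame_index: int
    found: bool
    centroid_x: float = math.nan
    centroid_y: float = math.nan
    rect_cx: float = math.nan
    rect_cy: float = math.nan
    rect_w: float = math.nan
    rect_l: float = math.nan
    rect_angle: float = math.nan
    area: float = math.nan

    def with_index(self, frame_index: int) -> "FrameDetection":
        return replace(self, frame_index=frame_index)


NOT_FOUND = FrameDetection(frame_index=-1, found=False)


def threshold_frame(frame: np.ndarray, rng: HsvRange) -> np.ndarray:
    """Binary mask of pixels whose HSV triple lies inside ``rng``."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected an H×W×3 colour raster, got {frame.shape}")
    hsv = rgb2hsv(frame)
    hue = hsv[..., 0] * 360.0
    return (rng.hue_mask(hue)
            & (hsv[..., 1] >= rng.s_low) & (hsv[..., 1] <= rng.s_high)
            & (hsv[..., 2] >= rng.v_low) & (hsv[..., 2] <= rng.v_high))


# 8-connectivity, as contour-following object detection uses.
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _min_rotated_rect(filled: np.ndarray, y0: int, x0: int):
    """Minimum rotated rectangle over the pixel-square corners of a region.

    Each mask pixel is treated as a unit square centred on its integer
    coordinate; the rectangle is the rotating-calipers minimum over the
    corners of the boundary pixels (interior corners cannot touch the hull).
    Returns (cx, cy, width, length, angle_deg).
    """
    boundary = filled & ~ndimage.binary_erosion(filled, structure=_STRUCT8)
    ys, xs = np.nonzero(boundary)
    xs = xs + x0
    ys = ys + y0
    corners = np.empty((xs.size * 4, 2), dtype=float)
    for i, (dx, dy) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        corners[i::4, 0] = xs + dx
        corners[i::4, 1] = ys + dy
    rect = shapely.minimum_rotated_rectangle(MultiPoint(corners))
    coords = np.asarray(rect.exterior.coords)[:4]
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    d1, d2 = np.hypot(*e1), np.hypot(*e2)
    long_edge = e1 if d1 >= d2 else e2
    length, width = max(d1, d2), min(d1, d2)
    angle = math.degrees(math.atan2(long_edge[1], long_edge[0])) % 180.0
    cx, cy = coords.mean(axis=0)
    return float(cx), float(cy), float(width), float(length), float(angle)


def find_largest_object(mask: np.ndarray,
                        min_area: float = DEFAULT_MIN_AREA) -> FrameDetection:
    """Largest connected object in a binary mask, or a not-found record.

    Objects are 8-connected components of the mask with interior holes
    filled ("outermost contour" semantics); ``area`` is the filled pixel
    count.  Components below ``min_area`` are ignored.  Equal areas are
    broken deterministically by top-most, then left-most bounding-box
    origin.
    """
    mask = np.asarray(mask).astype(bool)
    labels = label(mask, connectivity=2)
    best = None
    best_key = None
    for prop in regionprops(labels):
        # 8-connected foreground pairs with 4-connected background, so holes
        # are filled with the default (cross-shaped) structuring element
        filled = ndimage.binary_fill_holes(prop.image)
        a = float(filled.sum())
        if a < min_area:
            continue
        key = (-a, prop.bbox[0], prop.bbox[1])
        if best_key is None or key < best_key:
            best, best_key = (prop, filled, a), key
    if best is None:
        return NOT_FOUND

    prop, filled, area = best
    y0, x0 = prop.bbox[0], prop.bbox[1]
    ys, xs = np.nonzero(filled)
    cx = float(xs.mean() + x0)
    cy = float(ys.mean() + y0)
    rcx, rcy, rw, rl, ang = _min_rotated_rect(filled, y0, x0)
    return FrameDetection(
        frame_index=-1, found=True,
        centroid_x=cx, centroid_y=cy,
        rect_cx=rcx, rect_cy=rcy, rect_w=rw, rect_l=rl, rect_angle=ang,
        area=area,
    )


def detect_in_frame(frame: np.ndarray, rng: HsvRange,
                    crop: CropRect | None = None,
                    min_area: float = DEFAULT_MIN_AREA) -> FrameDetection:
    """Threshold → largest-object on one (optionally cropped) frame.

    Output coordinates are in cropped-frame space when a crop is given.
    """
    if crop is not None:
        frame = crop_frame(frame, crop)
    return find_largest_object(threshold_frame(frame, rng), min_area)
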