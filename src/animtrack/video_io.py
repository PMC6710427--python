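"""Video decoding, cropping and spatial calibration.

Coordinate convention used throughout the package: origin at the top-left
corner, x rightward (columns), y downward (rows), 0-based integer pixel
indices; sub-pixel positions (centroids, rectangle centres) live in the same
frame with pixel centres at integer coordinates.

Uncompressed RIFF/AVI files are decoded by the built-in codec
(:mod:`animtrack._avi`); any other container is handed to imageio, which will
use whatever decoding plugin is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from ._avi import AviError, read_avi

__all__ = [
    "VideoSource",
    "CropRect",
    "ScaleCalibration",
    "VideoDecodeError",
    "open_video",
    "crop_frame",
    "calibrate_scale",
]


class VideoDecodeError(RuntimeError):
    """A video file could not be opened or contains no frames."""


@dataclass(frozen=True)
class CropRect:
    """Axis-aligned crop rectangle in full-frame pixel coordinates."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.w < 1 or self.h < 1:
            raise ValueError(f"invalid crop rectangle {self}")

    def validate_against(self, width: int, height: int) -> None:
        if self.x + self.w > width or self.y + self.h > height:
            raise ValueError(
                f"crop {self} exceeds frame bounds {width}x{height}")


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixels-per-millimetre factor from a reference of known length.

    ``pixels_per_mm == 1`` with ``reference_mm == reference_pixels`` denotes
    an uncalibrated run whose "mm" outputs are really pixels.
    """

    pixels_per_mm: float
    reference_pixels: float
    reference_mm: float

    @property
    def calibrated(self) -> bool:
        return not (self.reference_pixels == self.reference_mm
                    and self.pixels_per_mm == 1.0)


IDENTITY_SCALE = ScaleCalibration(1.0, 1.0, 1.0)


def calibrate_scale(reference_pixels: float, reference_mm: float) -> ScaleCalibration:
    """Derive the px/mm factor from a drawn reference of known physical size."""
    if not (reference_pixels > 0 and reference_mm > 0):
        raise ValueError(
            f"calibration lengths must be positive, got "
            f"{reference_pixels} px / {reference_mm} mm")
    return ScaleCalibration(reference_pixels / reference_mm,
                            reference_pixels, reference_mm)


class VideoSource:
    """A decoded video: metadata plus an in-order frame iterator.

    Frames are H×W×3 uint8 RGB rasters, yielded in strictly increasing index
    order starting at 0.  Greyscale material is rejected: colour thresholding
    is defined on three channels.
    """

    def __init__(self, path: str | Path, frames: np.ndarray, fps: float):
        frames = np.asarray(frames)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise VideoDecodeError(
                f"{path}: expected 3-channel colour frames, got shape {frames.shape}")
        if frames.shape[0] == 0:
            raise VideoDecodeError(f"{path}: video contains no frames")
        if fps <= 0:
            raise VideoDecodeError(f"{path}: non-positive frame rate {fps}")
        self.path = Path(path)
        self._frames = frames
        self.fps = float(fps)
        self.frame_count = int(frames.shape[0])
        self.height = int(frames.shape[1])
        self.width = int(frames.shape[2])

    def __iter__(self) -> Iterator[np.ndarray]:
        yield from self._frames

    def frame(self, index: int) -> np.ndarray:
        return self._frames[index]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"VideoSource({self.path.name!r}, {self.width}x{self.height}, "
                f"{self.fps} fps, {self.frame_count} frames)")


def open_video(path: str | Path, fps_override: float | None = None) -> VideoSource:
    """Decode a video file into a :class:`VideoSource`.

    Parameters
    ----------
    path
        MP4/AVI (or anything an installed imageio plugin decodes).
    fps_override
        Trust this frame rate instead of the container's; phone recordings
        commonly misreport fps.
    """
    p = Path(path)
    if not p.exists():
        raise VideoDecodeError(f"video file not found: {p}")
    try:
        data = read_avi(p)
        frames, fps = data.frames, data.fps
    except AviError:
        if p.suffix.lower() == ".avi":
            raise VideoDecodeError(
                f"cannot decode {p}: not an uncompressed RGB24 AVI and no "
                f"external decoder is available")
        frames, fps = _open_with_imageio(p)
    return VideoSource(p, frames, fps_override if fps_override else fps)


def _open_with_imageio(p: Path) -> tuple[np.ndarray, float]:
    import imageio.v3 as iio

    try:
        frames = np.asarray(iio.imread(p, index=None))
        meta = iio.immeta(p)
    except Exception as exc:
        raise VideoDecodeError(f"cannot decode {p}: {exc}") from exc
    fps = meta.get("fps") or meta.get("framerate")
    if not fps and meta.get("duration"):
        fps = 1000.0 / meta["duration"]  # GIF per-frame duration in ms
    if frames.ndim == 3:  # single frame
        frames = frames[None]
    if frames.shape[-1] == 4:
        frames = frames[..., :3]
    return frames, float(fps or 0.0)


def crop_frame(frame: np.ndarray, rect: CropRect) -> np.ndarray:
    """Return the sub-raster selected by ``rect``; out-of-bounds rectangles
    raise rather than clamp."""
    h, w = frame.shape[:2]
    rect.validate_against(w, h)
    return frame[rect.y:rect.y + rect.h, rect.x:rect.x + rect.w]
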