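"""Synthetic test videos with exact ground truth.

Renders moving coloured shapes (discs, ellipses with time-varying axes,
rectangles) over a uniform background and writes them as lossless
uncompressed AVI, together with a ground-truth CSV of the true per-frame
centroid and shape dimensions.  Every module downstream of decoding is
validated against these fixtures, so no animal footage is needed.

Shapes are rasterised without anti-aliasing — a pixel belongs to the shape
iff its centre satisfies the shape inequality — so mask geometry is exact
and sub-pixel tolerances are meaningful.  Optional seeded single-pixel salt
noise of the target colour stress-tests minimum-area rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from ._avi import write_avi

__all__ = [
    "Disc", "EllipseShape", "RectShape", "TrajectorySpec", "GroundTruth",
    "render_frames", "render_video", "make_linear_spec", "make_larva_spec",
    "make_noise", "spec_from_yaml",
]

HSV = tuple[float, float, float]  # hue degrees [0,360), s, v in [0,1]

RED: HSV = (0.0, 1.0, 1.0)
BLUE: HSV = (240.0, 1.0, 1.0)
WHITE: HSV = (0.0, 0.0, 1.0)
BLACK: HSV = (0.0, 0.0, 0.0)


def _per_frame(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"per-frame array must have length {n}, got {arr.shape}")
    return arr


@dataclass(frozen=True)
class Disc:
    radius: float

    def mask(self, xx, yy, cx, cy, t):
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius ** 2

    def extent(self, t):
        return self.radius

    def dims(self, t):
        return 2 * self.radius, 2 * self.radius


@dataclass(frozen=True)
class EllipseShape:
    """Axis lengths may be scalars or per-frame arrays; ``a`` is the
    semi-major, ``b`` the semi-minor axis, ``angle_deg`` the major-axis
    orientation."""

    a: float | np.ndarray
    b: float | np.ndarray
    angle_deg: float | np.ndarray = 0.0

    def _at(self, t):
        def pick(v):
            v = np.asarray(v, dtype=float)
            return float(v) if v.ndim == 0 else float(v[t])
        return pick(self.a), pick(self.b), pick(self.angle_deg)

    def mask(self, xx, yy, cx, cy, t):
        a, b, ang = self._at(t)
        th = np.deg2rad(ang)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def extent(self, t):
        a, b, _ = self._at(t)
        return max(a, b)

    def dims(self, t):
        a, b, _ = self._at(t)
        return 2 * max(a, b), 2 * min(a, b)


@dataclass(frozen=True)
class RectShape:
    w: float
    h: float

    def mask(self, xx, yy, cx, cy, t):
        return (np.abs(xx - cx) <= self.w / 2) & (np.abs(yy - cy) <= self.h / 2)

    def extent(self, t):
        return float(np.hypot(self.w, self.h) / 2)

    def dims(self, t):
        return max(self.w, self.h), min(self.w, self.h)


@dataclass(frozen=True)
class TrajectorySpec:
    """A fully-specified synthetic video: per-frame centre, shape program,
    target/background colours and container metadata."""

    centres: np.ndarray  # (n_frames, 2) float, (x, y)
    shape: Disc | EllipseShape | RectShape
    colour: HSV = RED
    background: HSV = WHITE
    fps: float = 30.0
    width: int = 320
    height: int = 240
    allow_exit: bool = False
    salt_density: float = 0.0
    salt_seed: int = 0
    turn_windows: tuple[tuple[int, int], ...] = ()  # (start, duration)

    def __post_init__(self) -> None:
        c = np.asarray(self.centres, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 1:
            raise ValueError("centres must be a (n_frames, 2) array")
        object.__setattr__(self, "centres", c)
        if not self.allow_exit:
            for t, (cx, cy) in enumerate(c):
                e = self.shape.extent(t)
                if (cx - e < -0.5 or cy - e < -0.5
                        or cx + e > self.width - 0.5 or cy + e > self.height - 0.5):
                    raise ValueError(
                        f"shape leaves the {self.width}x{self.height} frame at "
                        f"frame {t} (centre {cx},{cy}, extent {e}); set "
                        f"allow_exit to permit this")

    @property
    def n_frames(self) -> int:
        return self.centres.shape[0]

    def turn_flags(self) -> np.ndarray:
        flags = np.zeros(self.n_frames, dtype=bool)
        for start, dur in self.turn_windows:
            flags[start:start + dur] = True
        return flags


@dataclass(frozen=True)
class GroundTruth:
    """True per-frame geometry of a rendered spec."""

    frame: pd.DataFrame  # frame, cx, cy, length_px, width_px, turn

    @property
    def centroids(self) -> np.ndarray:
        return self.frame[["cx", "cy"]].to_numpy()

    @property
    def total_path_px(self) -> float:
        steps = np.diff(self.centroids, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    def write_csv(self, out: str | Path) -> None:
        self.frame.to_csv(out, index=False, lineterminator="\n")


def _colour_u8(hsv: HSV) -> np.ndarray:
    h, s, v = hsv
    rgb = hsv2rgb(np.array([[[h / 360.0, s, v]]], dtype=float))[0, 0]
    return np.round(rgb * 255.0).astype(np.uint8)


def ground_truth(spec: TrajectorySpec) -> GroundTruth:
    rows = []
    turns = spec.turn_flags()
    for t, (cx, cy) in enumerate(spec.centres):
        length, width = spec.shape.dims(t)
        rows.append({"frame": t, "cx": cx, "cy": cy,
                     "length_px": length, "width_px": width,
                     "turn": int(turns[t])})
    return GroundTruth(frame=pd.DataFrame(rows))


def render_frames(spec: TrajectorySpec) -> np.ndarray:
    """Rasterise the spec into an (n, h, w, 3) uint8 RGB array."""
    fg = _colour_u8(spec.colour)
    bg = _colour_u8(spec.background)
    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    frames = np.empty((spec.n_frames, spec.height, spec.width, 3), dtype=np.uint8)
    rng = np.random.default_rng(spec.salt_seed)
    n_salt = int(round(spec.salt_density * spec.width * spec.height))
    for t, (cx, cy) in enumerate(spec.centres):
        mask = spec.shape.mask(xx, yy, cx, cy, t)
        frame = np.where(mask[..., None], fg, bg).astype(np.uint8)
        if n_salt:
            occupied = mask.copy()
            placed = 0
            while placed < n_salt:
                x = int(rng.integers(1, spec.width - 1))
                y = int(rng.integers(1, spec.height - 1))
                # keep distractors isolated: no contact with the object or
                # other salt (8-neighbourhood), so each stays a 1 px² blob
                if occupied[y - 1:y + 2, x - 1:x + 2].any():
                    continue
                frame[y, x] = fg
                occupied[y - 1:y + 2, x - 1:x + 2] = True
                placed += 1
        frames[t] = frame
    return frames


def render_video(spec: TrajectorySpec, out: str | Path
                 ) -> tuple[Path, GroundTruth]:
    """Encode the spec losslessly at ``out`` (AVI) and write the ground
    truth beside it as ``<out>.ground_truth.csv``."""
    out = Path(out)
    frames = render_frames(spec)
    write_avi(out, frames, spec.fps)
    gt = ground_truth(spec)
    gt.write_csv(Path(str(out) + ".ground_truth.csv"))
    return out, gt


def make_linear_spec(start: tuple[float, float], velocity: tuple[float, float],
                     n_frames: int, radius: float = 8.0, fps: float = 30.0,
                     width: int = 320, height: int = 240,
                     colour: HSV = RED, background: HSV = WHITE,
                     sinusoid_amp: float = 0.0, sinusoid_period: float = 40.0,
                     ) -> TrajectorySpec:
    """Disc moving at constant velocity, optionally with a sinusoidal
    transverse (y) component."""
    t = np.arange(n_frames, dtype=float)
    x = start[0] + velocity[0] * t
    y = start[1] + velocity[1] * t
    if sinusoid_amp:
        y = y + sinusoid_amp * np.sin(2 * np.pi * t / sinusoid_period)
    return TrajectorySpec(centres=np.column_stack([x, y]), shape=Disc(radius),
                          colour=colour, background=background, fps=fps,
                          width=width, height=height)


def make_larva_spec(base_length: float = 40.0, stride_amp: float = 6.0,
                    period: float = 20.0,
                    turns: Sequence[tuple[int, int]] = (),
                    n_frames: int = 200, fps: float = 30.0,
                    width: int = 320, height: int = 240,
                    aspect: float = 4.0, turn_aspect: float = 1.5,
                    turn_length_factor: float = 0.6,
                    colour: HSV = RED, background: HSV = BLACK,
                    ) -> TrajectorySpec:
    """Pulsating-ellipse larva: body length oscillates sinusoidally
    (one cycle per ``period`` frames = one stride); during each declared
    turn window the larva "curls" — length shrinks by ``turn_length_factor``
    and the aspect ratio drops to ``turn_aspect``.

    The ground truth records the analytic length trace and turn flags.
    """
    if not stride_amp < base_length / 2:
        raise ValueError("stride_amp must be below half the base length")
    if period < 4:
        raise ValueError("period must be at least 4 frames")
    turns = tuple(tuple(t) for t in turns)
    spans = sorted((s, s + d) for s, d in turns)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError(f"turn windows overlap: {spans}")
    t = np.arange(n_frames, dtype=float)
    length = base_length + stride_amp * np.sin(2 * np.pi * t / period)
    ratio = np.full(n_frames, aspect)
    flags = np.zeros(n_frames, dtype=bool)
    for s, d in turns:
        flags[s:s + d] = True
    length = np.where(flags, length * turn_length_factor, length)
    ratio = np.where(flags, turn_aspect, ratio)
    a = length / 2.0
    b = length / (2.0 * ratio)
    centres = np.tile([width / 2.0, height / 2.0], (n_frames, 1))
    return TrajectorySpec(centres=centres,
                          shape=EllipseShape(a=a, b=b, angle_deg=0.0),
                          colour=colour, background=background, fps=fps,
                          width=width, height=height, turn_windows=turns)


def make_noise(spec: TrajectorySpec, salt_density: float,
               seed: int) -> TrajectorySpec:
    """Return a copy of ``spec`` with seeded single-pixel salt noise of the
    target colour (density = fraction of frame pixels per frame)."""
    if not 0.0 <= salt_density <= 1e-3:
        raise ValueError("salt_density must be in [0, 1e-3]")
    return replace(spec, salt_density=salt_density, salt_seed=int(seed))


def spec_from_yaml(path: str | Path) -> TrajectorySpec:
    """Build a spec from a YAML file mirroring TrajectorySpec field-for-field.

    Schema::

        width: 320
        height: 240
        fps: 30
        n_frames: 60
        colour: [0, 1, 1]          # HSV, hue in degrees
        background: [0, 0, 1]
        shape: {type: disc, radius: 8}           # or ellipse {a, b, angle_deg}
                                                 # or rectangle {w, h}
        motion: {start: [20, 120], velocity: [2, 0],
                 sinusoid_amp: 0, sinusoid_period: 40}
        # or explicit per-frame centres:
        # centres: [[20, 120], [22, 120], ...]
        salt_density: 0
        salt_seed: 0
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    n = int(cfg["n_frames"]) if "n_frames" in cfg else len(cfg["centres"])
    sh = cfg["shape"]
    kind = sh["type"]
    if kind == "disc":
        shape = Disc(float(sh["radius"]))
    elif kind == "ellipse":
        shape = EllipseShape(a=_per_frame(sh["a"], n), b=_per_frame(sh["b"], n),
                             angle_deg=float(sh.get("angle_deg", 0.0)))
    elif kind == "rectangle":
        shape = RectShape(float(sh["w"]), float(sh["h"]))
    else:
        raise ValueError(f"unknown shape type {kind!r}")
    if "centres" in cfg:
        centres = np.asarray(cfg["centres"], dtype=float)
    else:
        m = cfg["motion"]
        t = np.arange(n, dtype=float)
        x = m["start"][0] + m["velocity"][0] * t
        y = m["start"][1] + m["velocity"][1] * t
        if m.get("sinusoid_amp"):
            y = y + m["sinusoid_amp"] * np.sin(
                2 * np.pi * t / m.get("sinusoid_period", 40.0))
        centres = np.column_stack([x, y])
    return TrajectorySpec(
        centres=centres, shape=shape,
        colour=tuple(cfg.get("colour", RED)),
        background=tuple(cfg.get("background", WHITE)),
        fps=float(cfg.get("fps", 30.0)),
        width=int(cfg.get("width", 320)), height=int(cfg.get("height", 240)),
        salt_density=float(cfg.get("salt_density", 0.0)),
        salt_seed=int(cfg.get("salt_seed", 0)),
    )
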