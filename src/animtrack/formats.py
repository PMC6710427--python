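"""On-disk formats: path CSV, settings log, summary CSV, threshold presets.

All files are UTF-8 text with LF line endings, comma delimiter and ``.``
decimal, independent of locale, so runs are diffable across platforms.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .detection import DEFAULT_MIN_AREA, FrameDetection, HsvRange
from .tracking import PathSummary, TrackedPath
from .video_io import CropRect, IDENTITY_SCALE, ScaleCalibration, calibrate_scale

__all__ = [
    "PATH_CSV_COLUMNS",
    "write_path_csv",
    "read_path_csv",
    "write_settings",
    "read_settings",
    "append_summary",
    "read_preset",
    "write_preset",
]

PATH_CSV_COLUMNS = [
    "frame", "found", "centroid_x", "centroid_y",
    "rect_cx", "rect_cy", "rect_w", "rect_l", "rect_angle", "area",
]

SUMMARY_COLUMNS = ["video_id", "n_frames", "total_distance_mm",
                   "scaling_factor", "n_detected"]


def path_to_frame(path: TrackedPath) -> pd.DataFrame:
    rows = []
    for d in path.detections:
        rows.append({
            "frame": d.frame_index, "found": int(d.found),
            "centroid_x": d.centroid_x, "centroid_y": d.centroid_y,
            "rect_cx": d.rect_cx, "rect_cy": d.rect_cy,
            "rect_w": d.rect_w, "rect_l": d.rect_l,
            "rect_angle": d.rect_angle, "area": d.area,
        })
    return pd.DataFrame(rows, columns=PATH_CSV_COLUMNS)


def write_path_csv(path: TrackedPath, out: str | Path) -> None:
    """Per-frame record of the run (the ``<video>.csv`` output)."""
    path_to_frame(path).to_csv(out, index=False, lineterminator="\n")


def read_path_csv(csv_path: str | Path, fps: float,
                  scale: ScaleCalibration = IDENTITY_SCALE,
                  video_id: str | None = None) -> TrackedPath:
    """Rebuild a :class:`TrackedPath` from a path CSV.

    fps and scale are not stored in the CSV (they live in the settings log),
    so the caller supplies them; analytics can then be re-run without the
    original video.
    """
    df = pd.read_csv(csv_path)
    missing = set(PATH_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path}: not a path CSV, missing columns {sorted(missing)}")
    dets = []
    for row in df.itertuples(index=False):
        found = bool(row.found)
        dets.append(FrameDetection(
            frame_index=int(row.frame), found=found,
            centroid_x=float(row.centroid_x), centroid_y=float(row.centroid_y),
            rect_cx=float(row.rect_cx), rect_cy=float(row.rect_cy),
            rect_w=float(row.rect_w), rect_l=float(row.rect_l),
            rect_angle=float(row.rect_angle), area=float(row.area),
        ) if found else FrameDetection(frame_index=int(row.frame), found=False))
    return TrackedPath(detections=tuple(dets), fps=fps, scale=scale,
                       video_id=video_id or Path(csv_path).stem)


def _fmt(v) -> str:
    return repr(float(v)) if isinstance(v, float) else str(v)


def write_settings(out: str | Path, *, video: str | Path, threshold: HsvRange,
                   crop: CropRect | None, scale: ScaleCalibration,
                   min_area: float, gap_policy: str,
                   fps_override: float | None = None) -> None:
    """Settings log (``<video>.settings.txt``): every parameter needed to
    reproduce the run bit-for-bit."""
    lines = [f"animtrack_version={__version__}", f"video={video}"]
    for k, v in asdict(threshold).items():
        lines.append(f"{k}={_fmt(v)}")
    lines.append("crop=" + (f"{crop.x},{crop.y},{crop.w},{crop.h}" if crop else "none"))
    lines.append(f"scale_px={_fmt(scale.reference_pixels)}")
    lines.append(f"scale_mm={_fmt(scale.reference_mm)}")
    lines.append(f"min_area={_fmt(float(min_area))}")
    lines.append(f"gap_policy={gap_policy}")
    lines.append("fps_override=" + (_fmt(fps_override) if fps_override else "none"))
    Path(out).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_settings(settings_path: str | Path) -> dict:
    """Parse a settings log back into run parameters.

    Returns a dict with keys ``video`` (Path), ``threshold`` (HsvRange),
    ``crop`` (CropRect | None), ``scale`` (ScaleCalibration), ``min_area``,
    ``gap_policy`` and ``fps_override``.
    """
    kv: dict[str, str] = {}
    for line in Path(settings_path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    threshold = HsvRange(**{k: float(kv[k]) for k in
                            ("h_low", "h_high", "s_low", "s_high", "v_low", "v_high")})
    crop = None
    if kv.get("crop", "none") != "none":
        x, y, w, h = (int(float(v)) for v in kv["crop"].split(","))
        crop = CropRect(x, y, w, h)
    scale = calibrate_scale(float(kv["scale_px"]), float(kv["scale_mm"]))
    fps_override = None if kv.get("fps_override", "none") == "none" \
        else float(kv["fps_override"])
    return {
        "video": Path(kv["video"]),
        "threshold": threshold,
        "crop": crop,
        "scale": scale,
        "min_area": float(kv.get("min_area", DEFAULT_MIN_AREA)),
        "gap_policy": kv.get("gap_policy", "bridge"),
        "fps_override": fps_override,
    }


def append_summary(summary_path: str | Path, summary: PathSummary) -> None:
    """Append one run to the analysis log (``animapp_summary.csv``);
    the file accumulates a row per run, never overwrites."""
    p = Path(summary_path)
    row = pd.DataFrame([asdict(summary)], columns=SUMMARY_COLUMNS)
    row.to_csv(p, mode="a", header=not p.exists(), index=False, lineterminator="\n")


_PRESET_KEYS = ("h_low", "h_high", "s_low", "s_high", "v_low", "v_high")


def read_preset(preset_path: str | Path, dialect: str = "degrees"
                ) -> tuple[HsvRange, float]:
    """Load a threshold preset file (plain ``key=value`` text).

    ``dialect="degrees"`` expects hue in [0, 360] and s/v in [0, 1];
    ``dialect="opencv"`` converts from the 0–179 hue / 0–255 s,v integer
    convention used by OpenCV-based tools.  The dialect is always explicit,
    never guessed.  Returns ``(range, min_area)``.
    """
    if dialect not in ("degrees", "opencv"):
        raise ValueError(f"unknown preset dialect {dialect!r}")
    kv: dict[str, float] = {}
    for line in Path(preset_path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = float(val.strip())
    missing = set(_PRESET_KEYS) - set(kv)
    if missing:
        raise ValueError(f"{preset_path}: preset missing keys {sorted(missing)}")
    vals = {k: kv[k] for k in _PRESET_KEYS}
    if dialect == "opencv":
        for k in ("h_low", "h_high"):
            vals[k] = vals[k] * 2.0  # 0–179 half-degrees
        for k in ("s_low", "s_high", "v_low", "v_high"):
            vals[k] = vals[k] / 255.0
    return HsvRange(**vals), float(kv.get("min_area", DEFAULT_MIN_AREA))


def write_preset(preset_path: str | Path, rng: HsvRange,
                 min_area: float = DEFAULT_MIN_AREA) -> None:
    lines = [f"{k}={_fmt(float(v))}" for k, v in asdict(rng).items()]
    lines.append(f"min_area={_fmt(float(min_area))}")
    Path(preset_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
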