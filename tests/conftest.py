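import math

import numpy as np
import pytest

from animtrack.detection import FrameDetection, HsvRange
from animtrack.synthetic import make_linear_spec, render_video
from animtrack.tracking import TrackedPath
from animtrack.video_io import IDENTITY_SCALE, ScaleCalibration


@pytest.fixture(scope="session")
def red_range() -> HsvRange:
    """Wrapped red window, the package's canonical target colour."""
    return HsvRange(350, 10, 0.5, 1.0, 0.5, 1.0)


@pytest.fixture(scope="session")
def blue_range() -> HsvRange:
    return HsvRange(220, 260, 0.5, 1.0, 0.5, 1.0)


@pytest.fixture(scope="session")
def linear_video(tmp_path_factory):
    """60-frame red disc moving 2 px/frame along x; returns (path, gt, spec)."""
    spec = make_linear_spec(start=(20, 120), velocity=(2, 0), n_frames=60,
                            radius=8)
    out = tmp_path_factory.mktemp("fixtures") / "linear.avi"
    path, gt = render_video(spec, out)
    return path, gt, spec


def build_path(xy, fps=30.0, scale: ScaleCalibration = IDENTITY_SCALE,
               frame_index=None, rect_l=None, rect_w=None,
               video_id="synthetic") -> TrackedPath:
    """Construct a TrackedPath directly from coordinates (and optionally a
    shape trace), bypassing video rendering.  NaN rows become not-found
    frames."""
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    idx = np.arange(n) if frame_index is None else np.asarray(frame_index)
    rect_l = np.full(n, math.nan) if rect_l is None else np.asarray(rect_l, float)
    rect_w = np.full(n, math.nan) if rect_w is None else np.asarray(rect_w, float)
    dets = []
    for i in range(n):
        x, y = xy[i]
        if math.isnan(x):
            dets.append(FrameDetection(frame_index=int(idx[i]), found=False))
        else:
            dets.append(FrameDetection(
                frame_index=int(idx[i]), found=True, centroid_x=x, centroid_y=y,
                rect_cx=x, rect_cy=y, rect_w=rect_w[i], rect_l=rect_l[i],
                rect_angle=0.0, area=max(rect_l[i] * rect_w[i], 1.0)
                if not math.isnan(rect_l[i]) else 1.0))
    return TrackedPath(detections=tuple(dets), fps=fps, scale=scale,
                       video_id=video_id)
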