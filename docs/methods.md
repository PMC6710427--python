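# Methods

## The tracking model

`animtrack` quantifies the locomotion of a single small animal (or a single
colour tag on an animal) filmed against a high-contrast, roughly uniform
background — a mouse on cage bedding, a *Drosophila* larva on an agar plate, a
coloured paw mark.  The model is deliberately simple and transparent:

1. Each frame is converted to HSV and thresholded against a user-set colour
   window.  Hue is in degrees [0, 360); a window with `h_low > h_high` wraps
   through 0°, which is required for red targets because red straddles the
   hue origin.  Bounds are inclusive in all three channels.
2. Connected objects in the binary mask (8-connected foreground, interior
   holes filled with the dual 4-connected background convention) are ranked
   by filled pixel area; the largest one at or above `min_area` is the
   animal.  There is no identity model: the method assumes at most one
   plausible target per frame per colour window.
3. The object's area-weighted centroid is its position.  Its minimum rotated
   rectangle — computed by rotating calipers over the corners of its boundary
   pixel squares — provides the shape record: the longer side is the animal's
   *length*, the shorter its *width*, plus the orientation angle of the
   length axis.
4. The per-frame records form a path.  Distance is the summed Euclidean step
   length between centroids of consecutive detected frames, divided by a
   pixels-per-mm calibration taken from a reference object of known physical
   size.  Uncalibrated runs use a factor of 1.0 and effectively report
   pixels.

Multi-colour videos (e.g. paws marked red and blue) are handled by running
the same single-target pipeline once per colour window over the same decoded
frame stream; crossing paths are unproblematic because each run is blind to
the other colours.

### Coordinates and conventions

Origin at the top-left corner, x rightward, y downward, 0-based pixel
indices; pixel centres sit at integer coordinates and each pixel spans ±0.5.
Crops are applied before thresholding, so all output coordinates are in
cropped-frame space; the crop offset is recorded in the settings log.
Greyscale input is rejected — the method is defined on colour.

### Failed detections and the gap policy

Frames where no object passes the threshold and area floor are recorded as
not-found and contribute no position.  When a gap of failed frames separates
two detections, the default `bridge` policy adds one straight-line step
across the gap — a lower bound on the distance actually travelled — while
`skip` excludes such steps entirely.  `n_detected` is reported next to
`n_frames` in every summary so detection quality is always visible.

## Kinematic analytics

**Instantaneous velocity.**  Each unbroken run of detected frames is tiled
with non-overlapping windows spanning `window_frames` steps (frames *t* …
*t* + `window_frames`); velocity is the window's travelled distance divided
by `window_frames`/fps seconds.  The default window of 10 frames corresponds
to 333 ms at 30 fps and scales correctly with other frame rates.  Windows
touching a failed detection are omitted, not interpolated.

**Distance binning.**  Step distances are histogrammed into half-open bins
[k·w, (k+1)·w) and also totalled per time bin.  Summed per-bin distance
equals total distance by construction (conservation), which the tests assert
to 1e-9 relative.

**Region occupancy.**  The fraction of detected frames whose centroid lies
inside a named axis-aligned rectangle, boundary counted as inside (so a
whole-frame region is exactly 1.0).  A path with zero detections raises an
undefined-occupancy error rather than returning 0 — "never there" and "never
seen" are different facts.

**Recording-length coefficient of variation.**  To choose the shortest
recording that still estimates a session's travel rate reliably, the path is
split into consecutive complete segments of each candidate duration, each
treated as its own recording: only steps with both endpoints inside a
segment count toward it, so boundary-crossing steps are dropped and a
uniform-motion path has CV exactly 0.  CV% = sample sd (ddof = 1) / mean of
the segment distances × 100.

**Path normalisation.**  Translation of the whole path so the first detected
centroid is (0, 0), for overlaying paths from different recordings; distances
are translation-invariant.

## Larval stride and turn analysis

A crawling larva extends and contracts peristaltically; its rectangle length
oscillates once per stride.  A turning larva curls, which shortens it and
widens it, dropping the length:width aspect ratio.

- The per-frame length trace is smoothed with a centred moving average
  (default window 5 frames, odd by construction; edge windows truncate).
- Local maxima and minima of the smoothed trace with prominence ≥
  `min_prominence_px` (default 2 px) are paired into (peak, following
  trough) stride events.  The trace is padded with a below-minimum sentinel
  before peak finding so a genuine extremum near the trace edge keeps its
  full prominence; noise wiggles are still rejected by their interior-side
  prominence.
- Each extremum is refined to the raw trace's extremum within half a
  smoothing window, and the amplitude is peak-to-trough on the **raw**
  trace, converted to mm.  Measuring on the smoothed trace would attenuate a
  period-20 sinusoid by ~10% (the moving-average transfer function), which
  is why the raw values are used.  Peak-to-trough was chosen over
  deviation-from-mean; halve the numbers for the latter.
- A frame is flagged as a turn when its aspect ratio falls below
  `ratio_turn_threshold` (default 0.6) × the video-median aspect ratio —
  the threshold is relative so it adapts to each animal's baseline
  elongation.  Stride events overlapping any turn frame are discarded.

Defaults (window 5, prominence 2 px, turn factor 0.6) are this package's
choices, exposed as parameters; they are not field-calibrated constants, and
real larvae with shallow contractions may need a lower prominence.

## Synthetic fixtures and what they do (not) show

The `synthetic` module renders discs, rotating/pulsating ellipses and
rectangles with exact per-frame ground truth (centroid, axis lengths, turn
flags), encoded losslessly, plus seeded single-pixel salt noise of the target
colour to exercise the `min_area` floor.  The larva fixture oscillates an
ellipse's major axis as L(t) = base + amp·sin(2πt/period) (defaults 40 ± 6 px,
period 20 frames, 200 frames, aspect ratio 4) and drops the aspect ratio to
1.5 during declared turn windows.

Fixtures are rendered without anti-aliasing over a perfectly uniform
background, so they validate the geometry and bookkeeping of the pipeline —
centroid recovery to sub-pixel RMS, distance to <2%, stride counts exactly —
but deliberately not robustness to lighting gradients, shadows, motion blur,
codec artefacts, fur texture or occlusion.  Passing tests demonstrate the
method is implemented correctly, not that a given cage video will threshold
cleanly; threshold quality on real footage remains the user's responsibility.

## Numerical choices and edge cases

- **Detection ties**: equal filled areas are broken by top-most, then
  left-most bounding-box origin — arbitrary but deterministic.
- **Area semantics**: filled pixel count of the component (outermost-contour
  reading); interior holes neither split the object nor reduce its area.
- **min_area** defaults to 20 px²; without it, a single salt pixel would win
  on frames where the animal is absent.
- **No morphological cleanup** is applied by default, keeping the default
  pipeline faithful to plain threshold-and-select behaviour.
- **Minimum-rectangle accuracy**: on rasterised shapes each axis reads ~1 px
  long because boundary pixel squares extend half a pixel beyond their
  centres.  For small, thin ellipses (minor axis ≲ 6 px) the *minimum-area*
  rectangle can legitimately sit diagonal to the major axis at some
  rotations, distorting length/width by up to ~30%; length-difference
  quantities (stride amplitudes) are unaffected at the fixture's sizes, but
  absolute aspect ratios of very thin targets should be treated with care.
- **Determinism**: the pipeline contains no randomness; identical inputs and
  parameters give byte-identical CSVs, and each settings log replays its run
  exactly.
- **Video decoding**: uncompressed RGB24 RIFF/AVI is decoded by the built-in
  codec; other containers are delegated to whatever imageio plugin is
  installed.  Synthetic fixtures are always written as uncompressed AVI so
  compression cannot perturb sub-pixel assertions.

## Verification problem sizes

The verification suite and `scripts/acceptance.py` use 320×240 videos:
ten 60-frame random-trajectory disc videos for centroid/distance recovery,
200-frame larva fixtures for stride and turn analysis, a 500-step random walk
for the distance-oracle comparison, and 6-minute-at-1-fps paths for the
segment-CV closed forms — sizes at which every quantity has an exact or
closed-form expectation.
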