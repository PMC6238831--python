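# Methods

`ulcermetrics` re-creates, as a desk-scale and fully testable toolkit, the
computational core of a phone-based self-monitoring workflow for diabetic
foot ulcers (DFUs): photograph the plantar foot under flash with a dark
background, calibrate physical scale from a 1-cm green fiducial sticker,
segment the foot and then the ulcer, and track wound size over weeks. This
note documents the models, the defaults and why they hold, and what the
synthetic fixtures do and do not demonstrate.

## Imaging model and synthetic scenes

The capture protocol is modeled photometrically, not photorealistically: the
flash illuminates the foot while the background stays dark, so scenes are
rendered as a bright skin-toned ellipse (Rec.601 luminance 178 by default) on
a dark background (luminance 15), with a reddish wound polygon, a
green-dominant sticker disc, an optional linear row-wise illumination ramp,
and optional i.i.d. Gaussian pixel noise clipped to 8 bits. A minimum
foot-background luminance contrast of 80 is enforced as part of the flash
model. Ground-truth masks are captured before noise is added, so they are
exact.

Geometry uses one convention everywhere: (row, col), 0-based, origin
top-left, integer coordinates at pixel centers. Polygons are rasterized by
the even-odd rule on pixel centers; for shapes of ≥ 400 px the rasterized
pixel count tracks the shoelace area within 3%, which bounds how exactly any
downstream area measurement can be expected to agree with analytic truth.
`SceneParams.foot_luminance` is an 8-bit scalar; the rendered foot color is
the fixture skin tone (210, 170, 140) rescaled so its luminance matches, a
fixture convenience with no claim about real skin.

Randomized scenes (`random_scene_params`) draw the foot ellipse, a
star-convex wound polygon (5–8 vertices, radii 14–26 px, vertex angles
evenly spaced with ±35% jitter so the outline is irregular but never a
degenerate sliver) on the toe side, and a sticker of radius 10–60 px placed
on intact skin toward the heel, kept inside the silhouette and at least
10 px clear of the wound. The sticker placement rule is a fixture choice;
the capture protocol itself only requires the sticker somewhere on the foot.

What the fixtures deliberately lack: skin texture, specular highlights,
shadows, perspective and tilt, dressings, calluses, and multi-wound feet.
Passing tests therefore demonstrate correctness of the algorithms under the
stated contrast model, not clinical segmentation accuracy on real
photographs.

## Scale calibration

The sticker is found by a pointwise green-dominance rule (G > 1.3·R,
G > 1.3·B, G ≥ 60) followed by 8-connected component filtering: area ≥ 50 px
and circularity 4πA/P² ≥ 0.7. The perimeter P is the weighted chain-code
estimator (`skimage.measure.perimeter`), which approximates the true contour
length of a digital shape; with the raw count of boundary edge segments a
perfect digital disc would score only π²/16 ≈ 0.62 and no circular sticker
could ever pass a 0.7 threshold, so the weighted estimator is the definition
used, under which discs score ≈ 0.92–0.96 and ragged noise blobs fall well
below 0.7. The sticker diameter is the equivalent-circle diameter
2·√(A/π) — robust to ragged rasterized edges — and pixels-per-cm is that
diameter divided by the 1-cm physical diameter. Detection fails loudly:
`NoStickerFound` when nothing survives, `AmbiguousSticker` when a runner-up
component is within 20% of the winner's area. All constants are exposed in
`PipelineConfig`.

## Foot segmentation

Only relative contrast is guaranteed, so the luminance threshold is chosen
per image by Otsu's method rather than fixed. A 3×3 binary opening
suppresses salt noise before the largest 8-connected component is kept, and
enclosed holes are filled so a wound bed darker than the threshold still
counts as foot — mandatory, because the ulcer/foot area ratio needs a
denominator that contains the wound. `NoFootFound` is raised when the
largest component covers under 2% of the frame. "Size of the foot" is taken
to be silhouette pixel area (not length or a template); this is an
assumption of this package, flagged as such.

## Ulcer segmentation: seeded priority-flood watershed

Two user strokes — one around the ulcer on skin, one inside it — are
rasterized to marker pixels (consecutive points joined by Bresenham lines;
overlapping strokes are an error). The relief is the per-pixel maximum
absolute luminance difference to the 4-neighbors: the minimal faithful
gradient for a marker watershed, chosen over color distance because
luminance is what the flash-contrast model controls.

The flood itself is defined exactly so that results are bit-reproducible:
a priority queue is initialized with the unlabeled 4-neighbors of all marker
pixels (markers visited in row-major order, neighbors in up/down/left/right
order); the entry with the lowest relief is popped, FIFO among equal relief
by insertion order; an unlabeled popped pixel takes the label of the
neighbor that enqueued it and enqueues its own unlabeled neighbors. There is
no separate ridge label — the application needs a filled wound area, not a
crest line — and pixels outside the foot silhouette are pre-assigned the
skin label before flooding so the wound cannot leak into the background.
The test suite checks this flood, pixel for pixel, against an independent
brute-force implementation that re-scans a plain list for the minimum on
every pop.

The wound boundary is traced with Moore-neighbor tracing, clockwise from
the topmost-then-leftmost boundary pixel, terminated by Jacob's criterion
(stop when the initial move repeats), and drawn onto the photo as a pure
green contour.

## Wound metrics and healing assessment

A measurement records the date, pixel areas, the calibrated scale, the area
in cm² (pixels / ppcm²), and the ulcer/foot area ratio — the latter is
scale-free and thus robust to camera distance, which is why it is the
quantity tracked across visits. Percent-of-baseline curves divide by the
earliest measurement (start of care, not minimum area).

The healing classification uses the established clinical surrogate: a
greater-than-50% reduction in ulcer area within the first 4 weeks of care
predicts effective healing. The assessment point is the measurement nearest
baseline + 28 days accepted within ±3 days (nearest wins, earlier wins
ties); the comparison is strictly greater than 50%, so an exact 50.0%
reduction is classified not-on-track. The 28-day target, ±3-day window and
threshold are configurable; the windowing rule is this package's own, since
the surrogate marker literature states only the 4-week horizon.

Reminders are pure arithmetic: the next due time is anchor + k·interval for
the smallest k ≥ 1 strictly after "now", so a query exactly on a due time
returns the following one. Dates serialize as ISO-8601; the default message
is "Time to check your foot".

## Capture guidance

The phone lies camera-up on the floor. Each frame yields the silhouette's
areal fraction of the frame and its centroid offset. Decision order: no
foot → NO_FOOT; fraction above the band → HIGHER (a large silhouette means
the foot is too close to an upward-facing camera, so the instruction is to
raise it — this direction convention is a documented choice of this
package); below the band → LOWER; off-center beyond the tolerance → CENTER;
otherwise the frame is compliant and a counter advances, emitting HOLD until
k consecutive compliant frames trigger CAPTURED, at most once per session.
Any non-compliant frame resets the counter.

Defaults: fraction band 0.25–0.45, center tolerance 10% of the smaller image
dimension, k = 3. With the default sweep camera (focal constant 130 px,
24-cm foot, 240×320 frames) the band corresponds to hover heights of roughly
13–17 cm, a comfortable distance for a floor-mounted phone. These are
engineering defaults for a concept demonstrator, not clinically validated
values.

## Numerical and testing choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every stage is bit-reproducible.
- Problem sizes in tests and in `scripts/acceptance.py`: 50 scenes of
  240×320 px per recovery experiment, 100 random 8×8 grids for the
  flood-oracle comparison, 5-point healing series, 30-frame guidance sweeps.
  These sizes give stable rates while a full run stays under a minute.
- Degenerate inputs are errors, not silent defaults: empty masks, missing
  markers, overlapping strokes, zero baselines and out-of-window assessments
  all raise typed exceptions that the CLI maps to distinct exit codes.
- Measurement-log appends are atomic (write to a temp file, then rename), so
  a failed analysis never leaves a partial row.

## Known limitations

- No perspective or tilt correction; an oblique sticker would bias the scale
  low and fails circularity rather than being fitted as an ellipse.
- Fully automatic (scribble-free) wound detection, tissue-type
  classification and infection scoring are out of scope.
- The guidance module emits symbolic tokens; speech synthesis, camera and
  flash control are platform concerns outside this package.
- Accuracy figures quoted by the tests apply to the synthetic contrast
  model; real flash photographs of skin will be harder in every respect.
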