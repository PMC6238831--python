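# ulcermetrics

A desk-scale toolkit for measuring diabetic foot ulcers (DFUs) from phone
photos. It implements the computational core of a self-monitoring workflow:
the patient photographs the plantar foot under flash against a dark
background with a 1-cm green fiducial sticker on the skin; the toolkit
calibrates physical scale from the sticker, segments the foot from the
background and the ulcer from the foot (seeded by two rough finger
scribbles), and turns the segmentations into dated wound measurements that
can be tracked across weeks of care. Everything runs on synthetic scenes
with exact ground truth, so the whole pipeline is testable without any
clinical images.

Intended users: researchers and engineers prototyping wound-photography
analytics, and anyone who needs a reproducible, dependency-light reference
for scribble-seeded watershed wound measurement.

## The measurements

With a sticker of physical diameter 1 cm detected at diameter *d* px, the
scale is *s = d* px/cm and a wound of *n* pixels has area

    A = n / s²  [cm²]

The scale-free companion is the area ratio *n / n_foot* (ulcer pixels over
filled foot-silhouette pixels), robust to camera distance. Healing is
assessed against the clinical surrogate marker of percent area reduction at
4 weeks:

    PAR = 100 · (A_baseline − A_week4) / A_baseline,   on-track ⇔ PAR > 50

The ulcer is segmented by a marker-seeded watershed: the two scribbles (one
around the wound on skin, one inside it) seed a priority flood over the
luminance-gradient relief, with exact FIFO tie-breaking so results are
bit-reproducible; the flood is verified against an independent brute-force
oracle in the test suite.

## Worked example

The one-command demo builds a 5-point synthetic healing series (a wound
starting at 2 cm² shrinking 25% per week), runs the full pipeline on every
time point, and assesses healing:

```
$ ulcermetrics demo --seed 1 --out demo_out
{
  "baseline_date": "2026-01-01",
  "baseline_area_cm2": 2.0006721712001827,
  "assessment_date": "2026-01-29",
  "assessment_area_cm2": 0.6335670148647674,
  "percent_reduction": 68.33229231730168,
  "on_track": true
}
```

The measured 68.3% reduction matches the closed form 100·(1 − 0.75⁴) =
68.4% to within rasterization error, and exceeds the 50% marker, so the
simulated wound is classified on-track. `demo_out/` contains each analyzed
image with its green boundary overlay, the measurement log
(`measurements.csv`), the progress plot (`progress.png`) and the assessment
report. Individual stages are available as subcommands:

```
$ ulcermetrics calibrate demo_out/day_000/image.png
{
  "pixels_per_cm": 40.005775929634204,
  ...
}
```

(The scene was rendered with a 20 px-radius sticker, i.e. a true scale of
40 px/cm.) Run `ulcermetrics --help` for the full list: `simulate`,
`calibrate`, `segment-foot`, `segment-ulcer`, `analyze`, `track`, `remind`,
`guide`, `demo`.

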