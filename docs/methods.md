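# Methods

## Geometry and coordinate conventions

The world frame has x along the driving direction and y across it, in
metres.  Image boxes use the raster convention: origin top-left, x
rightwards, y downwards, half-open `[x_min, x_min + width)`.  The image y
axis maps to *decreasing* world x, so the upper edge of an image is the far
edge of its ground footprint — which is where the error model concentrates
misses (over-illumination under the camera cover).  The paperless
alternative mapping (image x along track) is a config swap away; nothing
downstream depends on the choice.

Pixel-to-world conversion is a pure scale-and-translate under the
fixed-pixel-size assumption: no lens distortion, no homography, no GNSS
error model.  A frame's anchor (world position of its image origin) is
`trigger_index * trigger_spacing + fov_along_track` plus a per-camera
across-track offset, so consecutive footprints overlap by
`fov_along_track - trigger_spacing` exactly (0.28 m at the defaults).

The default rig: four cameras, 0.53 m x 0.70 m footprints, 2048 x 1536 px,
triggered every 0.25 m, non-overlapping across track.  A point can fall in
at most `floor(0.53 / 0.25) + 1 = 3` consecutive footprints; the typical
point falls in 2 (the 3-view fraction is `0.53/0.25 - 2 = 12%`).  Note the
53% along-track overlap implied by these numbers; a rig with a different
overlap is a config change.

## Post-processing

Raw detections (confidence = objectness x class score) are thresholded at
0.001 and then pruned by greedy class-wise NMS at IoU 0.5 (strictly
greater suppresses).  Ties in confidence are broken by input order for
determinism.  Degenerate zero-area boxes are rejected at construction.

## Image-level evaluation

One-to-one, class-aware greedy matching by descending confidence; a pair
matches when IoU > 0.5 (strict).  Greedy matching can differ from the
optimal assignment by at most one TP on adversarial scenes; tests flag
this explicitly.  Cross-class overlaps count as an FP for the detected
class and an FN for the annotated class.  Per-plot metrics come from
per-plot pooled counts, never from averaging per-image ratios; zero
denominators yield an `undefined` sentinel that is excluded from averages
rather than coerced to 0 or 1.

## Application-level (plant-level) evaluation

Per-frame ground-truth boxes are projected to world coordinates and fused
into plants by single-linkage clustering of box centres within
`link_radius = 0.09 m` (half the 0.19 m intra-row sowing distance: adjacent
beets can never fuse, while projection jitter and partial edge views still
link).  A plant's world box is the envelope of its projected views.

A potato-class detection *covers* a plant when intersection / plant-box
area >= 0.25 **or** the plant centre lies inside the detection.  The dual
criterion accepts both full enclosures (several plants under one box) and
partial splits (one plant under several boxes) while rejecting grazing
overlaps; the threshold is a config knob and is echoed in every report.
Counting rules, each plant counted exactly once:

* potato with >= 1 covering potato detection in any frame, from any
  camera: one TP (however many views or boxes support it);
* potato never covered: one FN;
* sugar beet covered by >= 1 potato detection: one crop FP — the sprayer
  would terminate it;
* a detection covering k potatoes yields k TPs; one overlapping k beets
  yields k crop FPs;
* potato detections covering no plant are background FPs; their world
  centroids are fused by single-linkage at `cluster_radius = 0.09 m` so a
  rock seen in three overlapping frames is one wasted-spray event, not
  three (clustering can be switched off).

Sugar-beet-class detections never trigger the sprayer and are ignored at
this level.  Composition fractions (shares of detection units hitting
potato / beet / background) denominate by `TP + crop FP + background FP`.

## Sprayer simulation and field-level scoring

The boom carries 29 nozzles at 9.5 cm pitch, each wetting a ~10 cm strip —
adjacent strips overlap slightly and are modelled literally, so the boom
covers its working width without gaps.  Every nozzle whose strip intersects
a detection's across-track extent activates over the detection's own
along-track extent, expanded when needed to the controller quantum
`speed x 10 ms` (the default speed is 0: instantaneous switching, since no
travel speed is part of the default scenario; the optional controller rate
limit of 5 detections/s is available as a drop-oldest queue but off by
default).  Duplicate detections from overlapping frames simply re-activate
the same nozzles; per-nozzle intervals are merged.

A plant is *hit* when its world box (optionally dilated by `hit_margin`,
default 0) intersects any activation rectangle.  A hit beet is *near a
potato* when its box lies within `near_radius = 0.10 m` (one section width)
of a hit potato's box — the share of crop damage attributable to the coarse
section resolution rather than to misclassification.  Plot percentages are
pooled as the unweighted mean of per-plot percentages, matching how such
field counts are usually tabulated; a count-weighted pooled row is reported
alongside.  Printed-style integer percentages round half away from zero,
only in formatters, never in stored values.

Two ordering laws connect the tiers and are enforced by tests: every
plant-level TP is sprayed (its covering detection activates sections over
their shared area), so the field-level kill rate is bounded below by the
plant-level recall; and shrinking the section width monotonically shrinks
the sprayed area and hence the collateral beet hits.

## Synthetic trials

The generator emulates an eight-plot trial: 2 m x 12.5 m plots, four on
sandy and four on peaty soil, barley cover on plots 1, 4, 5 and 8.  Beets
sit on the sowing lattice (4 rows, 0.5 m inter-row, 0.19 m intra-row,
`floor(12.5/0.19) + 1 = 66` per row) with ±1 cm placement jitter; 30–38
volunteer potatoes per plot are placed uniformly with >= 0.30 m separation
from each other and >= 0.18 m from any beet (a tuber dropped onto a sown
beet would not leave both plants intact; this also keeps plant identities
unambiguous for the evaluator).  Plant boxes are square, 9–15 cm.  Per-frame
ground truth is the plant's world box clipped to the footprint, annotated
when at least half the plant is visible — partially visible edge plants
appear exactly as an annotator would record them.  With these sizes the
default plot yields potato annotation counts inside the 57–87 range of the
reference trial manifest shipped with the package.

Detector errors are phenomenological (no pixels are rendered):

| parameter | default | what it emulates |
|---|---|---|
| `miss_prob_base` | 0.235 | ordinary per-view misses |
| `miss_prob_top_edge` / `top_edge_fraction` | 0.92 / 0.30 | over-illumination band at the image top |
| `box_jitter_sigma_m` | 0.006 | localization noise |
| `merge_prob` / `merge_distance_m` | 0.03 / 0.30 | adjacent potatoes fused into one box |
| `split_prob` | 0.03 | one potato reported as two boxes |
| `beet_as_potato_prob` | 0.004 | crop misclassified as weed |
| `background_fp_rate_per_m2` | 0.15 (x2 on peat) | unknown weeds/rocks detected as potato |
| `background_miss_prob` | 0.70 | background objects detected inconsistently |

The defaults are a **calibration preset**: they were chosen so the pooled
image-level precision/recall of the potato class lands near 0.84/0.57 on
the default scenario, giving the package a working point with realistic
error volume.  They are not measurements of any real detector, and the
application- and field-level numbers that follow from them (plant recall
~0.87, crop FP ~0.7%, field kill ~87%, beet hits ~3%) are emergent, not
fitted.  Confidence draws are uniform in per-outcome ranges; everything
flows from one integer seed, with an independent stream per plot so plots
are reproducible in isolation.

What the synthetic trials do *not* contain: rendered imagery and hence any
real detector behaviour, correlated misses across views (each view is an
independent Bernoulli draw, which is what makes the closed-form
`1 - p^v` recovery experiment meaningful and is optimistic relative to,
e.g., a plant that is simply too small to detect in every view), trigger
jitter (available, default off), lens distortion, and navigation error.
Passing tests therefore demonstrate the correctness of the *evaluation
machinery* and the qualitative error phenomenology, not field performance
of any detector.

## Numerical choices

* IoU is clamped to [0, 1] against float round-off; boxes in different
  reference frames never compare.
* World/image round-trips are exact to < 1e-9 m; a 1e-6 px tolerance at
  the image border absorbs conversion round-off.
* Footprint membership is half-open, consistent with the box convention;
  a point exactly on a frame anchor belongs to that frame.  The view
  *maximum* (frame multiplicity) counts closed containment, since the
  boundary point is the one seen the maximal number of times.
* Single-linkage clustering uses a KD-tree for pair finding and sparse
  connected components for labelling; results are order-independent.
* All report files are UTF-8, POSIX newlines, sorted keys and
  full-precision floats: identical runs are byte-identical.

## Problem sizes

The default trial (8 plots, ~1700 frames, ~2400 plants, ~6000 annotations)
evaluates in a few seconds.  The recall-recovery experiment pools 100
single-plot scenes (~300 three-view potatoes), putting 3 binomial standard
errors at about ±4 percentage points around the 93.6% expectation.

## Known limitations

* Greedy image-level matching (the community convention) is not optimal
  assignment; tests bound the gap at one TP on small scenes.
* Background-FP deduplication across frames is a modelling choice (one FP
  per physical object); per-detection counting is available via
  `dedupe_background: false`.
* The coverage criterion (0.25 / centre containment) is a judgement call
  where visual inspection has no numeric rule; it is a reported,
  configurable parameter.
* Plot percentages pooled as unweighted means over-weight sparse plots;
  the count-weighted alternative is always emitted alongside.
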