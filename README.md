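# sprayeval

Three-tier evaluation of crop/weed detection systems for plant-specific
spraying, built around the use case of eliminating volunteer potatoes
(a legally notifiable weed in Dutch sugar-beet fields) with an autonomous
spot sprayer.

## The problem

Weed detectors are conventionally scored per image: a detection is a true
positive when it overlaps a ground-truth box of the same class with
IoU > 0.5, and precision = TP/(TP+FP), recall = TP/(TP+FN).  A spraying
robot, however, does not act on images — it acts on *plants*.  Its cameras
overlap ~50% or more along the driving direction, so each plant is seen up
to three times, and the sprayer triggers greedily on the first potato
detection.  Image metrics therefore systematically misjudge the machine:
a plant missed in two views but caught in the third is sprayed correctly, a
single box over two adjacent potatoes sprays both, and a box on bare soil
wastes herbicide without harming any crop — errors that all look the same
(or wrong) at image level.

`sprayeval` scores the same detections at three levels:

1. **Image level** — classic one-to-one IoU matching (greedy by detection
   confidence) with per-plot and pooled precision/recall.
2. **Application (plant) level** — per-frame ground truths are fused into
   world-coordinate plants; a potato with ≥1 associated potato detection in
   *any* frame is one TP, a never-detected potato one FN, a sugar beet hit
   by a potato detection one crop FP (counted once however many boxes hit
   it), and unassociated detections are clustered into per-object background
   FPs.  Merged and split boxes are resolved by their spraying consequence.
3. **Field level** — a simulator of the 29-nozzle boom (9.5 cm pitch,
   ~10 cm sections, 10 ms switching) turns detections into per-nozzle
   activation intervals and counts sprayed potatoes, hit beets, and hit
   beets attributable to the coarse section resolution.

A synthetic generator produces eight-plot field trials (beets on a
0.5 m x 0.19 m sowing lattice, potatoes at random positions, four cameras
with 0.53 m x 0.70 m footprints triggered every 0.25 m) and detector output
with realistic error structure (misses concentrated near the upper image
edge, box jitter, merges, splits, beet-as-potato confusions, soil-dependent
background false positives), so the whole stack is testable end-to-end
without field imagery.

## Worked example

```python
from sprayeval import RunConfig, run_in_memory

res = run_in_memory(RunConfig(seed=1))

img = res.image_report.pooled["potato"]
app = res.application_report.pooled
fld = res.field_report
print(f"image level:        precision {img.precision:.2f}  recall {img.recall:.2f}")
print(f"application level:  potato recall {app.potato_recall:.2f}  "
      f"crop FPs {app.beet_fp}  background FPs {app.background_fp}")
print(f"field level:        potatoes sprayed {fld.potatoes_sprayed_pct_mean:.0f}%  "
      f"beets hit {fld.beets_hit_pct_mean:.1f}%")
```

prints

```
image level:        precision 0.87  recall 0.57
application level:  potato recall 0.87  crop FPs 15  background FPs 20
field level:        potatoes sprayed 87%  beets hit 3.2%
```

Read bottom-up: the detector finds only 57% of the potato *annotations*,
yet 87% of the potato *plants* are detected at least once across their
overlapping views and hence sprayed; of the detector's mistakes, only 15
out of 2112 sugar beets (0.7%) would be terminated, while 20 detections hit
soil or unknown weeds — wasted herbicide, not crop damage.  The coarse
nozzle sections then hit slightly more beets (3.2%) than the plant-level
count predicts, most of them because they grow next to a sprayed potato.

The same pipeline runs from the shell, reading/writing COCO-style ground
truth, YOLO-style detection text files and CSV/JSON reports:

```sh
sprayeval all --seed 1 --out runs/demo
sprayeval report --manifest runs/demo/manifest.csv
```

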