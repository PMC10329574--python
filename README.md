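# polypval

Validation-metric sensitivity analysis for polyp detection in colonoscopy
images.

Reported performance of a polyp detector is not a property of the detector
alone: it depends on the **localization criterion** (what counts as "found"),
its **threshold**, the **assignment strategy** resolving ambiguous matches,
the **test center** the data came from, and the **polyp size distribution**.
`polypval` is a toolkit for quantifying exactly that sensitivity. It is aimed
at challenge organizers, method developers and reviewers in endoscopic image
analysis who need to know how much of a reported number is detector and how
much is validation design.

## What it computes

A detector's output on image *i* is a set of boxes with confidences; the
reference annotation is a set of binary polyp masks. A **localization
criterion** decides hit/miss per (prediction, reference) pair:

* overlap-based: IoU = |A∩B|/|A∪B| between the predicted box and the
  reference **box**, **mask**, or **convex hull**, with a hit iff IoU ≥ τ
  (strict `> 0` at τ = 0, so "any overlap" is expressible);
* point-based: the predicted box center lies inside the reference box /
  mask / hull;
* center distance: ‖c_pred − c_ref‖ ≤ τ pixels.

Ambiguities are resolved greedily in descending confidence (the COCO
convention). From the resulting object-level TP/FP/FN the toolkit derives

* Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP),
  F_β = (1+β²)·PPV·Sens/(β²·PPV+Sens) at a fixed confidence cutoff;
* **AP** — 101-point interpolated Average Precision over the pooled
  descending-confidence sweep — at single thresholds (AP@0.5, AP@0.75),
  threshold ranges (AP@0.5:0.95), and full threshold sweeps;
* per-center panels with across-center min/max/SD;
* AP stratified by polyp size (small < 100² px, large > 200² px at
  1920×1080, scaled with image area) with COCO-style "ignore" semantics and
  across-center sample SD;
* agreement of each criterion with binary clinician usefulness ratings.

Because the original multi-center data cannot be redistributed, the package
includes a **seeded synthetic study generator**: six centers with realistic
frame counts and prevalences, elliptical (protruded) and crescent-shaped
(flat, non-convex) polyp masks, and a detector stand-in with size-dependent
misses, localization jitter, scale noise, false positives and
confidence noise. Everything is deterministic under a fixed seed.

## Worked example

```python
from polypval import (LocalizationCriterion, criterion_comparison,
                      size_stratified_ap)
from polypval.synth import default_study_spec, generate_study

ds = generate_study(default_study_spec(seed=1))   # 1512 images, 6 centers

table = criterion_comparison(ds, [
    LocalizationCriterion("box_iou", 0.5),
    LocalizationCriterion("point_in_box"),
    LocalizationCriterion("point_in_mask"),
], confidence_cutoff=0.5)
print(table.round(3).to_string(index=False))
```

prints (seed 1):

```
    criterion  tp  fp  fn  sensitivity   ppv    f1    f2    ap
 box_iou>=0.5 664  51 776        0.461 0.929 0.616 0.513 0.679
 point_in_box 703  12 737        0.488 0.983 0.652 0.543 0.897
point_in_mask 673  42 767        0.467 0.941 0.625 0.520 0.726
```

The same predictions score 0.679 AP under the strict box-IoU criterion and
0.897 under the position-only criterion — the configuration, not the
detector, moved the number. Size stratification shows the second effect:

```python
rep = size_stratified_ap(ds, "box_iou")
print(rep.table[rep.table.center_id == "all"].round(3).to_string(index=False))
```

```
center_id size_class  n_references  ap@0.5  ap@0.5:0.95
      all      small           490   0.250        0.055
      all     medium           486   0.694        0.219
      all      large           464   0.877        0.381
```

A fixed ~25 px localization error is cheap on a 300-px polyp and fatal on a
70-px one, so AP@0.5 spans 0.25–0.88 across size classes for one and the
same detector model.

The same analyses are available from the shell:

```sh
polypval generate --seed 1 --out data/
polypval evaluate --data data/ --criterion box_iou --threshold 0.5 \
         --confidence-cutoff 0.5 --out reports/
polypval sweep --data data/ --kinds box_iou,mask_iou,hull_iou --out reports/
polypval stratify --data data/ --out reports/
polypval compare --data data/ --out reports/
polypval agree --data data/ --out reports/
```

Reports are plain CSV/JSON and embed the resolved configuration, seed and
toolkit version; reruns with the same seed are byte-identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default six-center study from the seed and runs every
pipeline stage end to end — per-center panel, size-stratified AP,
criterion comparison, threshold sweep and clinician-agreement analysis —
printing each report and writing the results JSON.

## Layout

| module | contents |
| --- | --- |
| `polypval.datamodel` / `polypval.io` | validated dataset model; COCO-dialect JSON and mask-PNG-directory readers/writers |
| `polypval.geometry` | boxes, raster regions, convex hulls, centroids, IoU, point membership |
| `polypval.matching` | localization criteria, greedy assignment, confusion counts |
| `polypval.metrics` | Sensitivity/PPV/F-beta, PR curves, 101-point AP, threshold sweeps |
| `polypval.study` | per-center panels, size stratification, criterion comparison, clinician agreement |
| `polypval.synth` | seeded synthetic multi-center study generator |
| `polypval.cli` | `polypval` command-line interface |

See `docs/methods.md` for the underlying models, defaults and limitations.
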