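# Methods

This note documents the conventions, models and design choices behind
`polypval`, in the spirit of a methods section: what is computed, under which
assumptions, and what a passing test does and does not establish.

## Pixel geometry

Coordinates are 0-based pixel indices. Boxes are half-open integer rectangles
`[x0, x1) × [y0, y1)`, so areas and box–box IoU are exact integer arithmetic.
A mask pixel `(r, c)` occupies the unit square `[c, c+1) × [r, r+1)`; its
center is `(c + 0.5, r + 0.5)`.

**Convex hull.** The hull of a mask is the convex hull of the union of its
foreground unit squares (equivalently, of all pixel corners), rasterized by
pixel-center inclusion with the boundary counting as inside. This definition
— rather than a hull of pixel *centers* — guarantees the containment chain
`mask ⊆ hull ⊆ bounding box` as pixel sets even for single-pixel or collinear
masks, which in turn forces the monotone ordering of the point-in-mask /
point-in-hull / point-in-box criteria. The rasterization uses a scanline
fill: hull vertices are integers and scanlines run at half-integers, so a
scanline never meets a vertex or horizontal edge; an epsilon of 1e-9 keeps
centers lying exactly on a slanted edge inside (true clearances are at least
`1/(2·dy)` for our coordinate ranges). The tests verify the scanline raster
equals a brute-force point-in-polygon oracle on random masks.

**Point membership** floors both coordinates: a point on an exact pixel
boundary belongs to the pixel to its lower-right. Deterministic tie-break,
no epsilon tuning.

**Reference center.** The center-distance criterion measures to the mask
centroid by default — the criterion targets the *position* of the polyp, and
the centroid is robust to bounding-box slack around elongated or crescent
shapes. The bounding-box center is available as a configuration
(`reference_center="box_center"`) because the choice is genuinely
conventional.

## Criteria and matching

A criterion is `(kind, threshold)`. Overlap kinds hit iff `IoU ≥ τ` for
`τ > 0` and `IoU > 0` at `τ = 0`, so the permissive "any mask overlap"
criterion is expressible as threshold 0. Point kinds ignore the threshold;
center distance hits iff `d ≤ τ`.

Assignment is greedy: predictions in descending confidence (ties by
`pred_id`), each taking the best-scoring unmatched reference among its hits
(score ties by `ref_id`; point-kind indicator ties by smaller center
distance). Greedy-by-confidence is the convention of COCO-style AP tooling
and is prefix-stable: matching the top-k predictions equals restricting the
full ranked matching to its first k rows, which is what lets the PR sweep run
in one pass. Multi-polyp images are rare in this domain, so the assignment
strategy matters less than the criterion; optimal (Hungarian) assignment and
double-counting variants are deliberately out of scope.

Counting metrics are only reported together with their confidence cutoff
(default 0.5, always explicit in reports): whether the original counting
analyses filtered by confidence at all is not documented, so the cutoff is a
mandatory, visible parameter rather than a hidden constant.

## Average Precision

Predictions are pooled over all images of the evaluation scope (micro
pooling), ranked by descending confidence with `pred_id` tie-breaks so AP is
reproducible bit for bit. AP is the 101-point interpolated value: the mean
over recall grid {0, 0.01, …, 1} of the maximum precision at recall ≥ r
(0 where unattainable). All-point (area-under-envelope) interpolation exists
behind a flag for sensitivity analysis but is never the default. `Fβ = 0`
when precision = recall = 0; PPV on zero predictions is *absent* (an error /
NaN), never silently 0. AP@a:b means the arithmetic mean of AP over
thresholds a, a+0.05, …, b.

Correctness of AP is anchored by two independent oracles in the test suite:
a brute-force implementation that re-matches every rank prefix from scratch
and scans the envelope explicitly, and an independent re-implementation of
the COCO evaluator's accumulate algorithm (cumulative TP/FP plus a
searchsorted envelope) for the box-mask setting. The binary COCO evaluator
package itself is not installable in this environment, so the second oracle
stands in for it.

## Size stratification

Size classes follow the small < 100², large > 200² px convention at
1920×1080, with thresholds scaled by image area for other resolutions.
Per-class AP uses COCO "ignore" semantics: the matching runs against *all*
references, and predictions matched to an out-of-class reference are removed
from that class's ranked sweep rather than counted as false positives —
naive FP counting would punish a detector for correctly finding polyps of
another size. "All centers" cells are pooled (micro) computations; the SD in
parentheses is the sample SD (n−1) across per-center values. With a single
center the SD is reported absent (NaN), never 0.

## Synthetic study generator

The generator emulates the *statistical structure* of a six-center
single-frame colonoscopy test collection, not its pixels: geometry and labels
only, no photorealism, no video.

* **Centers.** The shipped default: 256/276/457/227/208/88 frames at
  prevalences 0.98/0.89/0.99/0.64/0.99/0.94, 1920×1080, patients assigned
  round-robin (~4 images per patient). Polyp-bearing images get one polyp
  (two with probability 0.05).
* **Masks.** Ellipses (convex; labeled *protruded*) and crescents — an
  ellipse minus an off-center elliptical bite carving into the middle of the
  shape (non-convex; labeled *flat*). The central bite makes the box center
  fall in the concavity often enough that the point-in-mask and
  point-in-hull criteria disagree on ≥ 5% of predictions, so the
  reference-shape phenomenon is actually exercised. Default shape mixture
  0.7 ellipse / 0.3 crescent. Areas are truncated log-normals inside each
  size-class interval (medians 5 000 / 20 000 / 75 000 px² at reference
  resolution, σ = 0.5/0.4/0.4, 15% interior margins absorbing rasterization
  error near class boundaries); the size mixture is uniform (1/3 each) so
  the three stratified cells are comparably powered.
* **Detector stand-in.** Each reference is missed with probability
  `1/(1 + (area/400)²)` — a logistic in log-area with midpoint 20² px and
  slope 2. The midpoint is deliberately tiny: modern detectors fail mostly
  by *mislocalizing*, not by producing no box, so recall ceilings stay
  nearly flat across size classes and the size effect in AP is carried by
  localization error. Kept predictions take the true bounding box, shift its
  center by Gaussian jitter, rescale by a log-normal factor (σ = 0.10), and
  clip to the canvas. Poisson false positives (0.1/image, log-normal sizes,
  Beta(2,5) confidences) are appended. Confidence of a kept prediction is
  `clip(mask IoU + N(0, 0.1), 0, 1)`, so ranking correlates with quality the
  way trained detectors' confidences do.
* **Jitter modes.** `absolute` (default): SD 25 px at 1080p regardless of
  object size — a fixed localization error that costs small polyps far more
  IoU than large ones. This is the mechanism that produces the
  small < medium < large AP ordering. `relative`: SD = 0.18·√area, the
  negative control under which the IoU distribution is scale-free and the
  ordering collapses. Defaults were frozen after a pilot calibration and
  not revisited: 25 px is roughly a third of a small polyp's side, and 0.18
  makes the relative mode match the absolute mode at the medium-class
  median area.
* **Ratings.** A prediction is rated *useful* iff it hits any same-image
  reference under a generating criterion (default: mask IoU > 0, the
  position-focused reading of clinical usefulness), then flipped with
  probability `label_noise`. Real clinician ratings are judgments, not
  criterion evaluations; the simulator supports criterion-recovery
  experiments, not claims about clinicians.
* **Determinism.** One named `numpy` generator per stage; `generate_study`
  derives stage seeds as seed, seed+1, seed+2. Fixed seed ⇒ byte-identical
  datasets and reports.

**What a green synthetic test establishes.** That the *metrics machinery*
behaves as claimed (orderings, monotonicities, oracle equalities,
determinism) and that the stated generative mechanisms produce the published
qualitative phenomena. It does not establish the published absolute numbers:
those depend on a trained ensemble and real data the package does not ship.
Mean-level checks on stochastic quantities (e.g. the negative control's gap
collapse) are asserted on means over 10 seeds, since per-seed values carry
Monte-Carlo noise.

## Numerical and degenerate-case choices

* Recall/precision points and the 101-grid comparisons are exact floating
  doubles (`k/n` and `i/100` agree bitwise whenever mathematically equal),
  so no tolerance is needed in the AP envelope.
* Empty masks, degenerate boxes, dangling identifiers and duplicate ratings
  are rejected at construction with named errors; the CLI maps error classes
  to distinct exit codes.
* Prevalence and PPV raise on empty scopes rather than returning 0.
* Predictions may extend beyond the canvas only during generation; they are
  clipped back. On-disk boxes are `[x, y, w, h]` (COCO convention) and
  converted to half-open corners on load.
* Mask encodings accepted on read: polygons (rasterized by pixel-center
  inclusion) and uncompressed column-major RLE; writing always emits RLE,
  canonically key-sorted, so write∘read∘write is byte-stable.

## Known limitations

* The greedy assignment is the only strategy; rankings under optimal
  assignment could differ on multi-polyp images.
* The agreement analysis treats a rated prediction as hit/miss against *any*
  same-image reference; it does not model which polyp the clinician meant.
* Crescent masks are a geometric proxy for flat polyps; real flat-polyp
  masks have irregular boundaries and lower annotator agreement, neither of
  which is modeled.
* The linear mixed-effects analysis of localization quality on size/type is
  out of scope; `per_object_table` exports the per-object table (score, size
  class, type, center/patient/image hierarchy) for an external fit.
* The miss-rate midpoint is an absolute pixel area: at much lower
  resolutions than 1080p the same physical polyp is likelier to be missed,
  which is intended (detectors see pixels), but means cross-resolution
  comparisons of the *generator* are not scale-free.
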