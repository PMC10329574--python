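"""Counting metrics, PR curves and Average Precision.

The AP oracles here are deliberately independent of the library's sweep:
``bruteforce_ap`` re-matches every rank prefix from scratch per image and
builds the 101-point interpolated envelope by explicit scanning.
"""

import numpy as np
import pytest

from polypval import (
    Box,
    ConfusionCounts,
    Dataset,
    LocalizationCriterion,
    ap_range_mean,
    ap_threshold_sweep,
    average_precision,
    f_beta,
    match_image,
    ppv,
    pr_curve,
    sensitivity,
)
from polypval.errors import UndefinedValueError, UsageError
from polypval.synth import generate_study

from _utils import image, mask_from_strings, pred, ref, small_study_spec


# ---------------------------------------------------------------------------
# independent AP oracle
# ---------------------------------------------------------------------------

def bruteforce_ap(ds: Dataset, crit: LocalizationCriterion) -> float:
    """101-point AP by re-matching each rank prefix from scratch."""
    ranked = sorted(ds.predictions, key=lambda p: (-p.confidence, p.pred_id))
    refs_by_img = ds.references_by_image()
    n_refs = len(ds.references)
    points = []
    for k in range(1, len(ranked) + 1):
        prefix = ranked[:k]
        tp = 0
        for image_id, refs in refs_by_img.items():
            preds_here = [p for p in prefix if p.image_id == image_id]
            tp += len(match_image(preds_here, refs, crit).matches)
        points.append((tp / n_refs, tp / k))
    total = 0.0
    for i in range(101):
        r = i / 100
        best = 0.0
        for rec, prec in points:
            if rec >= r and prec > best:
                best = prec
        total += best
    return total / 101


def cocoeval_style_ap(boxes_gt, boxes_dt, threshold: float) -> float:
    """AP the way COCOeval computes it, for box ground truths on one or more
    images: per-image greedy best-IoU matching in global score order, then
    cumulative TP/FP and a searchsorted 101-point precision envelope.

    ``boxes_gt``: {image_id: [Box, ...]};  ``boxes_dt``: [(image_id, Box, score)].
    """
    def iou(a: Box, b: Box) -> float:
        iw = min(a.x1, b.x1) - max(a.x0, b.x0)
        ih = min(a.y1, b.y1) - max(a.y0, b.y0)
        if iw <= 0 or ih <= 0:
            return 0.0
        inter = iw * ih
        return inter / (a.area + b.area - inter)

    order = sorted(range(len(boxes_dt)), key=lambda i: -boxes_dt[i][2])
    matched = {img: [False] * len(gts) for img, gts in boxes_gt.items()}
    tps, fps = [], []
    for i in order:
        img, box, _ = boxes_dt[i]
        best, best_g = threshold - 1e-12, -1
        for g, gt in enumerate(boxes_gt.get(img, [])):
            if matched[img][g]:
                continue
            v = iou(box, gt)
            if v > best:
                best, best_g = v, g
        if best_g >= 0:
            matched[img][best_g] = True
            tps.append(1)
            fps.append(0)
        else:
            tps.append(0)
            fps.append(1)
    n_gt = sum(len(g) for g in boxes_gt.values())
    tp = np.cumsum(tps)
    fp = np.cumsum(fps)
    rc = tp / n_gt
    pr = tp / (tp + fp)
    # envelope from the right, then sample the 101 recall thresholds
    for i in range(len(pr) - 1, 0, -1):
        pr[i - 1] = max(pr[i - 1], pr[i])
    rec_thrs = np.linspace(0, 1, 101)
    inds = np.searchsorted(rc, rec_thrs, side="left")
    q = np.zeros(101)
    for ri, pi in enumerate(inds):
        if pi < len(pr):
            q[ri] = pr[pi]
    return float(q.mean())


def random_instance(rng, boxes_only: bool):
    """Tiny random dataset: <= 5 images, <= 4 objects each."""
    images, refs, preds = [], [], []
    for i in range(rng.integers(1, 6)):
        img_id = f"i{i}"
        images.append(image(img_id, 24, 24, f"c{i % 2}", f"p{i}"))
        for j in range(rng.integers(0, 5)):
            x0, y0 = rng.integers(0, 14, 2)
            w, h = rng.integers(2, 9, 2)
            w = min(int(w), 24 - int(x0))
            h = min(int(h), 24 - int(y0))
            if boxes_only:
                m = np.ones((h, w), bool)
            else:
                m = rng.random((h, w)) < 0.6
                if not m.any():
                    m[0, 0] = True
            refs.append(ref(f"i{i}r{j}", img_id,
                            __import__("polypval").RasterRegion(
                                "mask", int(x0), int(y0), m)))
        for j in range(rng.integers(0, 6)):
            x0, y0 = rng.integers(0, 16, 2)
            w, h = rng.integers(2, 9, 2)
            preds.append(pred(f"i{i}d{j}", img_id,
                              Box(int(x0), int(y0),
                                  min(int(x0 + w), 24), min(int(y0 + h), 24)),
                              round(float(rng.random()), 6)))
    if not refs:  # AP needs at least one reference
        refs.append(ref("r_fix", images[0].image_id,
                        mask_from_strings("11", "11", x0=1, y0=1)))
    return Dataset(images=images, references=refs, predictions=preds)


# ---------------------------------------------------------------------------
# counting metrics
# ---------------------------------------------------------------------------

class TestCountingMetrics:
    def test_sensitivity_extremes(self):
        assert sensitivity(ConfusionCounts(5, 0, 0)) == 1.0
        assert sensitivity(ConfusionCounts(0, 3, 7)) == 0.0
        with pytest.raises(UndefinedValueError):
            sensitivity(ConfusionCounts(0, 3, 0))

    def test_ppv_extremes_and_undefined(self):
        assert ppv(ConfusionCounts(5, 0, 0)) == 1.0
        assert ppv(ConfusionCounts(0, 4, 1)) == 0.0
        with pytest.raises(UndefinedValueError):
            ppv(ConfusionCounts(0, 0, 4))

    def test_published_style_scaled_counts(self):
        # Sens 68/100 and PPV 78/100 from object counts
        assert sensitivity(ConfusionCounts(68, 22, 32)) == pytest.approx(0.68)
        assert ppv(ConfusionCounts(78, 22, 30)) == pytest.approx(0.78)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_f_beta_of_equal_args(self, beta):
        assert f_beta(0.6, 0.6, beta) == pytest.approx(0.6)

    def test_f_beta_worked_examples(self):
        assert round(f_beta(0.78, 0.68, 1.0), 2) == 0.73
        assert round(f_beta(0.78, 0.68, 2.0), 2) == 0.70

    def test_f2_closer_to_recall_than_f1(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p, r = rng.uniform(0.05, 1.0, 2)
            if abs(p - r) < 1e-6:
                continue
            f1 = f_beta(p, r, 1.0)
            f2 = f_beta(p, r, 2.0)
            assert abs(f2 - r) < abs(f1 - r)

    def test_f_beta_dual_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p, r = rng.uniform(0.0, 1.0, 2)
            beta = float(rng.uniform(0.2, 5.0))
            assert f_beta(p, r, beta) == pytest.approx(f_beta(r, p, 1 / beta))

    def test_f_beta_zero_convention_and_bounds(self):
        assert f_beta(0.0, 0.0, 1.0) == 0.0
        with pytest.raises(UsageError):
            f_beta(1.2, 0.5, 1.0)
        with pytest.raises(UsageError):
            f_beta(0.5, 0.5, 0.0)


# ---------------------------------------------------------------------------
# PR curve / AP
# ---------------------------------------------------------------------------

def three_ref_tp_fp_tp() -> Dataset:
    """3 references; ranked prediction outcomes TP, FP, TP."""
    images = [image("i1"), image("i2")]
    refs = [ref("r1", "i1", mask_from_strings("1111", "1111", x0=0, y0=0)),
            ref("r2", "i1", mask_from_strings("1111", "1111", x0=0, y0=10)),
            ref("r3", "i2", mask_from_strings("1111", "1111", x0=0, y0=0))]
    preds = [pred("p1", "i1", Box(0, 0, 4, 2), 0.9),     # TP on r1
             pred("p2", "i2", Box(20, 20, 26, 26), 0.8),  # FP
             pred("p3", "i1", Box(0, 10, 4, 12), 0.7)]   # TP on r2
    return Dataset(images=images, references=refs, predictions=preds)


class TestPRCurveAndAP:
    crit = LocalizationCriterion("box_iou", 0.5)

    def test_perfect_predictions(self):
        images = [image("i1")]
        refs = [ref("r1", "i1", mask_from_strings("1111", "1111", x0=2, y0=2))]
        preds = [pred("p1", "i1", Box(2, 2, 6, 4), 1.0)]
        ds = Dataset(images=images, references=refs, predictions=preds)
        curve = pr_curve(ds, self.crit)
        assert curve.points == ((1.0, 1.0),)
        assert average_precision(ds, self.crit) == 1.0

    def test_no_predictions(self):
        ds = Dataset(images=[image("i1")],
                     references=[ref("r1", "i1", mask_from_strings("11"))])
        assert pr_curve(ds, self.crit).points == ()
        assert average_precision(ds, self.crit) == 0.0

    def test_zero_references_undefined(self):
        ds = Dataset(images=[image("i1")],
                     predictions=[pred("p1", "i1", Box(0, 0, 2, 2), 0.5)])
        with pytest.raises(UndefinedValueError):
            pr_curve(ds, self.crit)

    def test_hand_enumerated_three_point_curve(self):
        curve = pr_curve(three_ref_tp_fp_tp(), self.crit)
        expected = ((1 / 3, 1.0), (1 / 3, 1 / 2), (2 / 3, 2 / 3))
        assert len(curve.points) == 3
        for got, want in zip(curve.points, expected):
            assert got == pytest.approx(want)

    def test_analytic_ap_56_over_101(self):
        # envelope: precision 1 on recall grid 0..0.33 (34 pts),
        # 2/3 on 0.34..0.66 (33 pts), 0 beyond -> (34 + 22) / 101
        ds = three_ref_tp_fp_tp()
        assert average_precision(ds, self.crit) == pytest.approx(56 / 101)
        assert bruteforce_ap(ds, self.crit) == pytest.approx(56 / 101)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(30):
            ds = random_instance(rng, boxes_only=False)
            crit = LocalizationCriterion(
                str(rng.choice(["box_iou", "mask_iou"])),
                float(rng.choice([0.1, 0.3, 0.5])),
            )
            assert average_precision(ds, crit) == bruteforce_ap(ds, crit)
            checked += 1
        assert checked == 30

    def test_ap_invariant_to_monotone_confidence_transform(self):
        from polypval import Prediction

        ds = generate_study(small_study_spec(seed=6, n_images=15))
        crit = LocalizationCriterion("box_iou", 0.5)
        base = average_precision(ds, crit)
        squashed = Dataset(
            images=list(ds.images), references=list(ds.references),
            predictions=[Prediction(p.pred_id, p.image_id, p.box,
                                    float(p.confidence ** 3))
                         for p in ds.predictions],
        )
        assert average_precision(squashed, crit) == pytest.approx(base)

    def test_all_points_interpolation_close_to_coco(self):
        ds = three_ref_tp_fp_tp()
        area = average_precision(ds, self.crit, interpolation="all_points")
        # exact area: 1/3 * 1 + 1/3 * 2/3 = 5/9
        assert area == pytest.approx(5 / 9)


class TestSweeps:
    def test_degenerate_range_equals_single_ap(self, small_study):
        ap_single = average_precision(small_study, LocalizationCriterion("box_iou", 0.5))
        assert ap_range_mean(small_study, "box_iou", 0.5, 0.5) == pytest.approx(ap_single)

    def test_range_mean_equals_mean_of_individual_aps(self, small_study):
        grid = [round(0.5 + 0.05 * i, 2) for i in range(10)]
        aps = [average_precision(small_study, LocalizationCriterion("box_iou", t))
               for t in grid]
        assert ap_range_mean(small_study, "box_iou", 0.5, 0.95) == pytest.approx(
            float(np.mean(aps))
        )

    def test_sweep_non_increasing(self, small_study):
        for kind in ("box_iou", "mask_iou", "hull_iou"):
            sweep = ap_threshold_sweep(small_study, kind)
            vals = [sweep[t] for t in sorted(sweep)]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_box_and_mask_sweeps_coincide_for_box_masks(self):
        rng = np.random.default_rng(23)
        ds = random_instance(rng, boxes_only=True)
        s_box = ap_threshold_sweep(ds, "box_iou")
        s_mask = ap_threshold_sweep(ds, "mask_iou")
        assert s_box == s_mask

    def test_non_overlap_kind_rejected(self, small_study):
        with pytest.raises(UsageError):
            ap_threshold_sweep(small_study, "point_in_mask")
        with pytest.raises(UsageError):
            ap_range_mean(small_study, "box_iou", 0.9, 0.5)
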