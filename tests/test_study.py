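"""Stratified reports, criterion comparison, clinician agreement."""

import math

import numpy as np
import pytest

from polypval import (
    Box,
    Dataset,
    LocalizationCriterion,
    UsefulnessRating,
    across_center_sd,
    agreement_fractions,
    criterion_comparison,
    per_center_panel,
    per_object_table,
    size_class,
    size_stratified_ap,
)
from polypval.errors import UsageError
from polypval.study import SizeClassRule
from polypval.synth import RatingModel, generate_study, simulate_ratings

from _utils import image, mask_from_strings, pred, ref, small_study_spec


def rect_ref(ref_id, image_id, x0, y0, w, h, polyp_type="protruded"):
    return ref(ref_id, image_id,
               mask_from_strings(*["1" * w] * h, x0=x0, y0=y0), polyp_type)


class TestSizeClass:
    def test_boundaries_at_reference_resolution(self):
        img = image("i1", 1920, 1080)
        small = rect_ref("r1", "i1", 0, 0, 99, 101)      # 9999 px
        boundary = rect_ref("r2", "i1", 0, 200, 100, 100)  # exactly 100^2
        large = rect_ref("r3", "i1", 300, 300, 250, 161)   # 40250 px
        assert size_class(small, img) == "small"
        assert size_class(boundary, img) == "medium"  # "the rest"
        assert size_class(large, img) == "large"

    def test_resolution_scaling(self):
        # at 960x540 the thresholds scale by 0.25 -> 2500 / 10000
        img = image("i1", 960, 540)
        r = rect_ref("r1", "i1", 0, 0, 61, 41)  # 2501 px
        assert size_class(r, img) == "medium"
        r2 = rect_ref("r2", "i1", 100, 100, 50, 49)  # 2450 px
        assert size_class(r2, img) == "small"

    def test_bad_rule_rejected(self):
        with pytest.raises(UsageError):
            SizeClassRule(small_max_area=400, large_min_area=300)


class TestPerCenterPanel:
    def test_single_center_equals_pooled(self):
        ds = generate_study(small_study_spec(seed=2, n_images=20, n_centers=1))
        rep = per_center_panel(ds)
        t = rep.table.set_index("center_id")
        for col in ("sensitivity", "ppv", "f1", "ap@0.5", "ap@0.5:0.95"):
            assert t.loc["c1", col] == pytest.approx(t.loc["all", col])

    def test_identical_centers_have_zero_sd(self):
        ds = generate_study(small_study_spec(seed=4, n_images=20, n_centers=1))
        # clone center c1 as c2 with relabeled ids
        from polypval import Dataset, ImageRecord, Prediction, ReferenceObject

        clone_imgs = [ImageRecord("x_" + im.image_id, im.width, im.height,
                                  "c2", im.patient_id) for im in ds.images]
        clone_refs = [ReferenceObject("x_" + r.ref_id, "x_" + r.image_id,
                                      r.mask, r.polyp_type) for r in ds.references]
        clone_preds = [Prediction("x_" + p.pred_id, "x_" + p.image_id, p.box,
                                  p.confidence) for p in ds.predictions]
        both = Dataset(images=list(ds.images) + clone_imgs,
                       references=list(ds.references) + clone_refs,
                       predictions=list(ds.predictions) + clone_preds)
        rep = per_center_panel(both)
        assert (rep.summary["sd"].fillna(0) == 0).all()
        assert (rep.summary["range"].fillna(0) == 0).all()

    def test_center_without_references_reported_absent(self):
        imgs = [image("i1", center_id="a"), image("i2", center_id="b")]
        refs = [rect_ref("r1", "i1", 2, 2, 4, 4)]
        preds = [pred("p1", "i1", Box(2, 2, 6, 6), 0.9)]
        rep = per_center_panel(Dataset(images=imgs, references=refs,
                                       predictions=preds))
        row_b = rep.table.set_index("center_id").loc["b"]
        assert math.isnan(row_b["sensitivity"]) and math.isnan(row_b["ap@0.5"])


class TestSizeStratifiedAP:
    def test_all_large_perfect_predictions(self):
        img = image("i1", 1920, 1080)
        r1 = rect_ref("r1", "i1", 0, 0, 300, 300)
        p1 = pred("p1", "i1", Box(0, 0, 300, 300), 0.9)
        rep = size_stratified_ap(Dataset(images=[img], references=[r1],
                                         predictions=[p1]))
        t = rep.table[rep.table.center_id == "all"].set_index("size_class")
        assert t.loc["large", "ap@0.5"] == 1.0
        assert math.isnan(t.loc["small", "ap@0.5"])
        assert math.isnan(t.loc["medium", "ap@0.5"])

    def test_ignore_semantics_protect_other_class_matches(self):
        # high-confidence prediction on the large polyp must not become a
        # false positive of the small-class sweep
        img = image("i1", 1920, 1080)
        refs = [rect_ref("r_lg", "i1", 0, 0, 300, 300),
                rect_ref("r_sm", "i1", 500, 500, 50, 50)]
        preds = [pred("p_lg", "i1", Box(0, 0, 300, 300), 0.9),
                 pred("p_sm", "i1", Box(500, 500, 550, 550), 0.2)]
        rep = size_stratified_ap(Dataset(images=[img], references=refs,
                                         predictions=preds))
        t = rep.table[rep.table.center_id == "all"].set_index("size_class")
        assert t.loc["small", "ap@0.5"] == 1.0
        assert t.loc["large", "ap@0.5"] == 1.0

    def test_per_size_counts_sum_to_total(self, small_study):
        rep = size_stratified_ap(small_study)
        pooled = rep.table[rep.table.center_id == "all"]
        assert pooled["n_references"].sum() == len(small_study.references)

    def test_sd_column_zero_for_single_center(self):
        ds = generate_study(small_study_spec(seed=8, n_images=25, n_centers=1))
        rep = size_stratified_ap(ds)
        # one center: sample SD undefined -> NaN, never a fabricated number
        assert rep.summary["ap@0.5 sd"].isna().all()

    def test_across_center_sd_is_sample_sd(self):
        vals = [0.73, 0.81, 0.91, 0.59, 0.59, 0.89]
        assert across_center_sd(vals) == pytest.approx(np.std(vals, ddof=1))
        assert across_center_sd([0.5, 0.5, 0.5]) == 0.0

    def test_non_overlap_kind_rejected(self, small_study):
        with pytest.raises(UsageError):
            size_stratified_ap(small_study, "point_in_box")


class TestCriterionComparison:
    def test_identical_predictions_all_criteria_perfect(self):
        img = image("i1", 100, 100)
        refs = [rect_ref("r1", "i1", 10, 10, 20, 20)]
        preds = [pred("p1", "i1", Box(10, 10, 30, 30), 1.0)]
        ds = Dataset(images=[img], references=refs, predictions=preds)
        crits = [LocalizationCriterion(k) for k in
                 ("box_iou", "mask_iou", "hull_iou", "point_in_box",
                  "point_in_mask", "point_in_hull")]
        table = criterion_comparison(ds, crits)
        assert (table[["sensitivity", "ppv", "f1", "f2", "ap"]] == 1.0).all().all()

    def test_point_in_mask_never_beats_point_in_box(self):
        for seed in range(5):
            ds = generate_study(small_study_spec(seed=seed, n_images=25))
            table = criterion_comparison(
                ds, [LocalizationCriterion("point_in_mask"),
                     LocalizationCriterion("point_in_box")]).set_index("criterion")
            assert (table.loc["point_in_mask", "sensitivity"]
                    <= table.loc["point_in_box", "sensitivity"])

    def test_box_iou_row_below_point_in_box_row(self, small_study):
        table = criterion_comparison(
            small_study,
            [LocalizationCriterion("box_iou", 0.5),
             LocalizationCriterion("point_in_box")]).set_index("criterion")
        for col in ("sensitivity", "ppv", "f1", "f2", "ap"):
            assert table.loc["box_iou>=0.5", col] <= table.loc["point_in_box", col]


class TestAgreement:
    def study_with_ratings(self, seed=31, criterion=None, noise=0.0):
        spec = small_study_spec(seed=seed, n_images=40)
        ds = generate_study(spec)
        model = RatingModel(
            generating_criterion=criterion or LocalizationCriterion("mask_iou", 0.0),
            label_noise=noise,
        )
        return simulate_ratings(ds, model, seed + 1000)

    def test_self_agreement_is_perfect(self):
        crit = LocalizationCriterion("point_in_mask")
        ds = self.study_with_ratings(criterion=crit)
        rep = agreement_fractions(ds, [crit])
        row = rep.table.iloc[0]
        assert row["frac_useful_accepted"] == 1.0
        assert row["frac_not_useful_rejected"] == 1.0

    def test_all_useful_none_hit(self):
        img = image("i1", 100, 100)
        refs = [rect_ref("r1", "i1", 10, 10, 10, 10)]
        preds = [pred("p1", "i1", Box(60, 60, 80, 80), 0.9)]
        ds = Dataset(images=[img], references=refs, predictions=preds,
                     ratings=[UsefulnessRating("p1", "useful", "x")])
        rep = agreement_fractions(ds, [LocalizationCriterion("box_iou", 0.5)])
        row = rep.table.iloc[0]
        assert row["frac_useful_accepted"] == 0.0
        assert math.isnan(row["frac_not_useful_rejected"])  # class empty

    def test_prediction_on_reference_free_image_counts_as_miss(self):
        imgs = [image("i1"), image("i2")]
        refs = [rect_ref("r1", "i1", 2, 2, 4, 4)]
        preds = [pred("p1", "i2", Box(0, 0, 4, 4), 0.9)]
        ds = Dataset(images=imgs, references=refs, predictions=preds,
                     ratings=[UsefulnessRating("p1", "not_useful", "x")])
        rep = agreement_fractions(ds, [LocalizationCriterion("point_in_box")])
        assert rep.table.iloc[0]["frac_not_useful_rejected"] == 1.0

    def test_generating_criterion_recovered(self):
        gen = LocalizationCriterion("mask_iou", 0.0)
        ds = self.study_with_ratings(criterion=gen)
        crits = [gen, LocalizationCriterion("box_iou", 0.5),
                 LocalizationCriterion("point_in_mask")]
        rep = agreement_fractions(ds, crits).table.set_index("criterion")
        summed = (rep["frac_useful_accepted"] + rep["frac_not_useful_rejected"])
        assert summed.idxmax() == gen.label()
        assert summed[gen.label()] == 2.0

    def test_requires_ratings(self, small_study):
        with pytest.raises(UsageError):
            agreement_fractions(small_study)


class TestPerObjectTable:
    def test_columns_and_hierarchy(self, small_study):
        tab = per_object_table(small_study)
        assert set(tab.columns) >= {"ref_id", "image_id", "patient_id",
                                    "center_id", "polyp_type", "area_px",
                                    "size_class", "best_score"}
        assert len(tab) == len(small_study.references)
        assert set(tab["polyp_type"]) <= {"flat", "protruded"}
        # every image has multiple rows only if it holds multiple polyps
        assert tab.groupby("center_id").size().sum() == len(tab)
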