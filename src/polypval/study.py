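"""Study-level analyses: the four sensitivity experiments.

* :func:`per_center_panel` — the standard metric set per validation center
  (sensitivity of results to the choice of test center).
* :func:`size_stratified_ap` — AP per center and polyp-size class with
  COCO-style "ignore" semantics, plus pooled values and across-center SD
  (sensitivity to the polyp-size distribution).
* :func:`criterion_comparison` — counting metrics and AP side by side for a
  list of localization criteria (point-based vs overlap-based).
* :func:`agreement_fractions` — agreement of each criterion with binary
  clinician usefulness ratings.

All reports are tidy :class:`pandas.DataFrame` tables wrapped in thin
dataclasses, ready for CSV/JSON serialization by the CLI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import Dataset, ImageRecord, ReferenceObject, prevalence
from .errors import UndefinedValueError, UsageError
from .matching import (
    OVERLAP_KINDS,
    LocalizationCriterion,
    confusion_counts,
    pair_score,
    raw_score,
)
from .metrics import (
    COCO_RANGE,
    EvaluationCache,
    _interpolated_ap,
    f_beta,
    metric_panel,
    ppv,
    sensitivity,
)

__all__ = [
    "AgreementReport",
    "SizeClassRule",
    "StratifiedReport",
    "across_center_sd",
    "agreement_fractions",
    "criterion_comparison",
    "default_agreement_criteria",
    "per_center_panel",
    "per_object_table",
    "size_class",
    "size_stratified_ap",
]

SIZE_CLASS_ORDER = ("small", "medium", "large")


def across_center_sd(values) -> float:
    """Sample standard deviation (ddof=1) across per-center metric values.

    NaN entries (centers where a metric is undefined, e.g. an empty size
    class) are skipped. This is the spread reported in parentheses next to
    pooled values in stratified tables.
    """
    return float(pd.Series(list(values), dtype=float).std(ddof=1))


@dataclass(frozen=True)
class SizeClassRule:
    """Polyp-size classes in pixels at a reference resolution.

    Small: area < ``small_max_area``; large: area > ``large_min_area``;
    medium: the rest. Thresholds scale with image area relative to the
    reference resolution, so the classes are resolution-independent.
    """

    small_max_area: int = 100 ** 2
    large_min_area: int = 200 ** 2
    reference_resolution: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        if not self.small_max_area < self.large_min_area:
            raise UsageError("small_max_area must be < large_min_area")


def size_class(ref: ReferenceObject, img: ImageRecord,
               rule: SizeClassRule = SizeClassRule()) -> str:
    scale = (img.width * img.height) / (
        rule.reference_resolution[0] * rule.reference_resolution[1]
    )
    if ref.area_px < rule.small_max_area * scale:
        return "small"
    if ref.area_px > rule.large_min_area * scale:
        return "large"
    return "medium"


@dataclass
class StratifiedReport:
    """A tidy per-stratum metric table plus an across-strata summary."""

    table: pd.DataFrame
    summary: Optional[pd.DataFrame] = None


@dataclass
class AgreementReport:
    """Per-criterion agreement with clinician usefulness ratings."""

    table: pd.DataFrame
    n_useful: int
    n_not_useful: int


# ---------------------------------------------------------------------------
# per-center panel
# ---------------------------------------------------------------------------

def _panel_row(scope: Dataset, crit: LocalizationCriterion, cutoff: float,
               label: str) -> dict:
    row: dict = {
        "center_id": label,
        "n_images": len(scope.images),
        "n_references": len(scope.references),
        "prevalence": prevalence(scope) if scope.images else math.nan,
        "confidence_cutoff": cutoff,
        "criterion": crit.label(),
    }
    metric_names = ["sensitivity", "ppv", "f1", "f2", "ap@0.5", "ap@0.75",
                    "ap@0.5:0.95"]
    if not scope.references:
        row.update({m: math.nan for m in metric_names})
        return row
    panel = metric_panel(scope, crit, cutoff)
    row["sensitivity"] = panel.sensitivity
    row["ppv"] = math.nan if panel.ppv is None else panel.ppv
    row["f1"] = panel.f1
    row["f2"] = panel.f2
    if crit.kind in OVERLAP_KINDS:
        row["ap@0.5"] = panel.ap_by_threshold[0.5]
        row["ap@0.75"] = panel.ap_by_threshold[0.75]
        row["ap@0.5:0.95"] = panel.ap_range_means[COCO_RANGE]
    else:
        row["ap@0.5"] = row["ap@0.75"] = row["ap@0.5:0.95"] = math.nan
        row["ap"] = panel.ap_by_threshold[crit.threshold]
    return row


def per_center_panel(ds: Dataset,
                     crit: LocalizationCriterion = LocalizationCriterion("box_iou", 0.5),
                     confidence_cutoff: float = 0.5) -> StratifiedReport:
    """Sensitivity/PPV/F1/F2 and AP@0.5, AP@0.75, AP@0.5:0.95 per center.

    The ``all`` row pools every center (micro); the summary holds the
    across-center min, max and range of each metric — the quantity of
    interest when arguing that results are center-sensitive.
    """
    centers = ds.center_ids()
    if not centers:
        raise UndefinedValueError("dataset has no centers")
    rows = [_panel_row(ds.subset_center(c), crit, confidence_cutoff, c)
            for c in centers]
    rows.append(_panel_row(ds, crit, confidence_cutoff, "all"))
    table = pd.DataFrame(rows)
    metric_cols = [c for c in ("sensitivity", "ppv", "f1", "f2", "ap@0.5",
                               "ap@0.75", "ap@0.5:0.95", "ap") if c in table]
    per_center = table[table["center_id"] != "all"]
    summary = pd.DataFrame(
        {
            "metric": metric_cols,
            "min": [per_center[c].min() for c in metric_cols],
            "max": [per_center[c].max() for c in metric_cols],
            "sd": [across_center_sd(per_center[c]) for c in metric_cols],
        }
    )
    summary["range"] = summary["max"] - summary["min"]
    return StratifiedReport(table=table, summary=summary)


# ---------------------------------------------------------------------------
# size-stratified AP
# ---------------------------------------------------------------------------

def _ap_ignoring_other_classes(cache: EvaluationCache, kind: str, threshold: float,
                               ref_class: dict[str, str], target: str) -> float:
    """AP restricted to one size class with COCO 'ignore' semantics.

    The full matching runs against *all* references; predictions matched to
    an out-of-class reference are removed from the ranked sweep (the detector
    is not punished for finding polyps of another size), unmatched
    predictions stay false positives, and recall is normalized by the
    in-class reference count.
    """
    n_refs = sum(1 for c in ref_class.values() if c == target)
    if n_refs == 0:
        return math.nan
    outcomes = cache.ranked_outcomes(LocalizationCriterion(kind, threshold))
    recalls, precisions = [], []
    tp = kept = 0
    for _, matched in outcomes:
        if matched is not None and ref_class[matched] != target:
            continue  # ignored: matched an out-of-class reference
        kept += 1
        if matched is not None:
            tp += 1
        recalls.append(tp / n_refs)
        precisions.append(tp / kept)
    return _interpolated_ap(np.array(recalls), np.array(precisions), "coco101")


def size_stratified_ap(ds: Dataset, crit_kind: str = "box_iou",
                       rule: SizeClassRule = SizeClassRule()) -> StratifiedReport:
    """AP@0.5 and AP@0.5:0.95 per center and polyp-size class.

    ``all`` rows pool every center (micro); the ``sd`` summary column is the
    sample SD (ddof=1) of the per-center values, the across-center spread the
    size-sensitivity analysis reports in parentheses.
    """
    if crit_kind not in OVERLAP_KINDS:
        raise UsageError(f"size stratification needs an overlap kind, got {crit_kind!r}")
    range_grid = [round(0.5 + 0.05 * i, 2) for i in range(10)]
    images = {im.image_id: im for im in ds.images}
    scopes = [(c, ds.subset_center(c)) for c in ds.center_ids()] + [("all", ds)]
    rows = []
    for label, scope in scopes:
        ref_class = {r.ref_id: size_class(r, images[r.image_id], rule)
                     for r in scope.references}
        cache = EvaluationCache(scope)
        for cls in SIZE_CLASS_ORDER:
            n_refs = sum(1 for c in ref_class.values() if c == cls)
            ap50 = _ap_ignoring_other_classes(cache, crit_kind, 0.5, ref_class, cls)
            ap_range = (
                float(np.mean([
                    _ap_ignoring_other_classes(cache, crit_kind, t, ref_class, cls)
                    for t in range_grid
                ]))
                if n_refs
                else math.nan
            )
            rows.append({
                "center_id": label,
                "size_class": cls,
                "n_references": n_refs,
                "ap@0.5": ap50,
                "ap@0.5:0.95": ap_range,
            })
    table = pd.DataFrame(rows)
    per_center = table[table["center_id"] != "all"]
    summary = (
        per_center.groupby("size_class", sort=False)[["ap@0.5", "ap@0.5:0.95"]]
        .agg(["mean", lambda s: across_center_sd(s)])
    )
    summary.columns = ["ap@0.5 mean", "ap@0.5 sd", "ap@0.5:0.95 mean",
                       "ap@0.5:0.95 sd"]
    return StratifiedReport(table=table, summary=summary.reset_index())


# ---------------------------------------------------------------------------
# criterion comparison
# ---------------------------------------------------------------------------

def criterion_comparison(ds: Dataset, criteria: Sequence[LocalizationCriterion],
                         confidence_cutoff: float = 0.5) -> pd.DataFrame:
    """Counting metrics and AP for each criterion on the pooled dataset."""
    if not criteria:
        raise UsageError("criterion_comparison needs at least one criterion")
    cache = EvaluationCache(ds)
    rows = []
    for crit in criteria:
        counts = confusion_counts(ds, crit, confidence_cutoff)
        sens = sensitivity(counts)
        try:
            prec: float = ppv(counts)
        except UndefinedValueError:
            prec = math.nan
        from .metrics import average_precision

        rows.append({
            "criterion": crit.label(),
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "sensitivity": sens,
            "ppv": prec,
            "f1": f_beta(prec, sens, 1.0) if not math.isnan(prec) else math.nan,
            "f2": f_beta(prec, sens, 2.0) if not math.isnan(prec) else math.nan,
            "ap": average_precision(ds, crit, cache=cache),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinician agreement
# ---------------------------------------------------------------------------

def default_agreement_criteria(ds: Dataset) -> list[LocalizationCriterion]:
    """The default criterion families for the agreement analysis.

    Position-focused: the three point-in-region criteria and center distance
    with tau set to the median equivalent radius (sqrt(area/pi)) of the
    dataset's references. Outline-focused: box/mask/hull IoU at 0.5 and the
    permissive ``mask_iou > 0`` (any mask overlap at all).
    """
    if ds.references:
        tau = float(np.median([math.sqrt(r.area_px / math.pi)
                               for r in ds.references]))
    else:
        tau = 50.0
    return [
        LocalizationCriterion("point_in_box"),
        LocalizationCriterion("point_in_mask"),
        LocalizationCriterion("point_in_hull"),
        LocalizationCriterion("center_distance", round(tau, 1)),
        LocalizationCriterion("box_iou", 0.5),
        LocalizationCriterion("mask_iou", 0.5),
        LocalizationCriterion("hull_iou", 0.5),
        LocalizationCriterion("mask_iou", 0.0),
    ]


def agreement_fractions(ds: Dataset,
                        criteria: Optional[Sequence[LocalizationCriterion]] = None
                        ) -> AgreementReport:
    """Fractions of clinician ratings each criterion agrees with.

    For each criterion: (a) the fraction of "useful"-rated predictions that
    hit at least one reference on their image, and (b) the fraction of
    "not_useful"-rated predictions that miss every reference. A prediction on
    an image without references can never be a hit. A fraction whose rating
    class is empty is reported as NaN (absent).
    """
    if ds.ratings is None:
        raise UsageError("dataset carries no usefulness ratings")
    criteria = list(criteria) if criteria is not None else default_agreement_criteria(ds)
    preds = {p.pred_id: p for p in ds.predictions}
    refs_by_img = ds.references_by_image()
    useful = [r.pred_id for r in ds.ratings if r.rating == "useful"]
    not_useful = [r.pred_id for r in ds.ratings if r.rating == "not_useful"]
    rows = []
    for crit in criteria:
        def hits(pred_id: str) -> bool:
            pred = preds[pred_id]
            return any(pair_score(pred, ref, crit).hit
                       for ref in refs_by_img[pred.image_id])

        n_acc = sum(hits(pid) for pid in useful)
        n_rej = sum(not hits(pid) for pid in not_useful)
        rows.append({
            "criterion": crit.label(),
            "n_useful": len(useful),
            "n_not_useful": len(not_useful),
            "useful_accepted": n_acc,
            "not_useful_rejected": n_rej,
            "frac_useful_accepted":
                n_acc / len(useful) if useful else math.nan,
            "frac_not_useful_rejected":
                n_rej / len(not_useful) if not_useful else math.nan,
        })
    return AgreementReport(table=pd.DataFrame(rows), n_useful=len(useful),
                           n_not_useful=len(not_useful))


# ---------------------------------------------------------------------------
# per-object export (for external hierarchical model fits)
# ---------------------------------------------------------------------------

def per_object_table(ds: Dataset, kind: str = "mask_iou",
                     rule: SizeClassRule = SizeClassRule()) -> pd.DataFrame:
    """One row per reference object, suitable for an external mixed-effects
    fit of localization quality on size/type with center, patient and image
    as grouping factors.

    ``best_score`` is the best raw score of any same-image prediction against
    the object under ``kind`` (NaN if the image has no predictions).
    """
    images = {im.image_id: im for im in ds.images}
    preds_by_img = ds.predictions_by_image()
    rows = []
    for ref in ds.references:
        img = images[ref.image_id]
        scores = [raw_score(p, ref, kind) for p in preds_by_img[ref.image_id]]
        rows.append({
            "ref_id": ref.ref_id,
            "image_id": ref.image_id,
            "patient_id": img.patient_id,
            "center_id": img.center_id,
            "polyp_type": ref.polyp_type,
            "area_px": ref.area_px,
            "size_class": size_class(ref, img, rule),
            "best_score": max(scores) if scores else math.nan,
        })
    return pd.DataFrame(rows)
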