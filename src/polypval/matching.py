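"""Localization criteria, hit/miss scoring and one-to-one assignment.

A :class:`LocalizationCriterion` is a ``(kind, threshold)`` pair. Overlap
kinds (``box_iou``, ``mask_iou``, ``hull_iou``) score a prediction against
the reference bounding box, segmentation mask or convex hull by IoU; point
kinds (``point_in_box``, ``point_in_mask``, ``point_in_hull``) test whether
the predicted box center lies inside the respective reference region;
``center_distance`` compares the distance between prediction and reference
centers against a pixel bound tau.

Hit rule for overlap kinds: ``score >= t`` for a threshold ``t > 0`` and
``score > 0`` at ``t == 0``, so "IoU > 0" (pure position agreement) is
expressible as threshold 0.

Ambiguities are resolved greedily: predictions in descending confidence order
each take the best still-unmatched hitting reference. This matches the
convention of COCO-style AP tooling and is deterministic (confidence ties
break by pred_id, score ties by ref_id; point-kind ties by smaller center
distance first, since the 0/1 indicator cannot rank candidates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .datamodel import Dataset, Prediction, ReferenceObject
from .errors import UsageError, ValidationError
from .geometry import (
    box_center,
    box_iou,
    center_distance,
    point_in_region,
    region_iou,
)

__all__ = [
    "ALL_KINDS",
    "OVERLAP_KINDS",
    "POINT_KINDS",
    "ConfusionCounts",
    "ImageMatching",
    "LocalizationCriterion",
    "PairScore",
    "confusion_counts",
    "match_image",
    "pair_score",
]

OVERLAP_KINDS = ("box_iou", "mask_iou", "hull_iou")
POINT_KINDS = ("point_in_box", "point_in_mask", "point_in_hull")
ALL_KINDS = OVERLAP_KINDS + POINT_KINDS + ("center_distance",)


@dataclass(frozen=True)
class LocalizationCriterion:
    """Rule deciding whether a prediction spatially hits a reference object.

    ``threshold`` is an IoU cutoff in [0, 1] for overlap kinds, a distance
    bound tau in pixels for ``center_distance``, and is ignored for point
    kinds. ``reference_center`` selects the reference center used by
    ``center_distance`` (mask centroid by default; ``"box_center"`` for the
    bounding-box center).
    """

    kind: str
    threshold: float = 0.5
    reference_center: str = "centroid"

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise UsageError(f"unknown criterion kind {self.kind!r}")
        if self.kind in OVERLAP_KINDS and not (0.0 <= self.threshold <= 1.0):
            raise UsageError(
                f"{self.kind} threshold {self.threshold} outside [0, 1]"
            )
        if self.kind == "center_distance" and self.threshold < 0:
            raise UsageError("center_distance bound tau must be >= 0")

    def label(self) -> str:
        if self.kind in POINT_KINDS:
            return self.kind
        if self.kind == "center_distance":
            return f"center_distance<={self.threshold:g}px"
        op = ">" if self.threshold == 0 else ">="
        return f"{self.kind}{op}{self.threshold:g}"


@dataclass(frozen=True)
class PairScore:
    """Raw similarity and the hit decision for one (prediction, reference) pair.

    The score is IoU for overlap kinds, a 0/1 indicator for point kinds, and
    the *negative* center distance for ``center_distance`` — larger is always
    better, so assignment can maximize uniformly.
    """

    pred_id: str
    ref_id: str
    score: float
    hit: bool


@dataclass
class ImageMatching:
    """One-to-one resolution of all (prediction, reference) pairs on an image."""

    matches: list[tuple[str, str]]
    unmatched_preds: list[str]
    unmatched_refs: list[str]


@dataclass(frozen=True)
class ConfusionCounts:
    """Object-level confusion counts. tp + fn = #references; tp + fp = #predictions."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def raw_score(pred: Prediction, ref: ReferenceObject, kind: str,
              reference_center: str = "centroid") -> float:
    """Criterion-kind score of a pair; larger is always better."""
    if kind == "box_iou":
        return box_iou(pred.box, ref.box)
    if kind == "mask_iou":
        return region_iou(pred.box, ref.mask)
    if kind == "hull_iou":
        return region_iou(pred.box, ref.hull)
    center = box_center(pred.box)
    if kind == "point_in_box":
        return float(point_in_region(center, ref.box))
    if kind == "point_in_mask":
        return float(point_in_region(center, ref.mask))
    if kind == "point_in_hull":
        return float(point_in_region(center, ref.hull))
    if kind == "center_distance":
        return -center_distance(pred.box, ref.mask, reference_center)
    raise UsageError(f"unknown criterion kind {kind!r}")


def score_is_hit(kind: str, score: float, threshold: float) -> bool:
    if kind in OVERLAP_KINDS:
        return score > 0.0 if threshold == 0.0 else score >= threshold
    if kind in POINT_KINDS:
        return score == 1.0
    # center_distance: score is -d, hit iff d <= tau
    return -score <= threshold


def pair_score(pred: Prediction, ref: ReferenceObject,
               crit: LocalizationCriterion) -> PairScore:
    """Score one pair under a criterion and decide hit/miss."""
    if pred.image_id != ref.image_id:
        raise UsageError(
            f"prediction {pred.pred_id!r} (image {pred.image_id!r}) scored against "
            f"reference {ref.ref_id!r} (image {ref.image_id!r})"
        )
    score = raw_score(pred, ref, crit.kind, crit.reference_center)
    return PairScore(pred.pred_id, ref.ref_id, score,
                     score_is_hit(crit.kind, score, crit.threshold))


def _ordered(preds: Sequence[Prediction]) -> list[Prediction]:
    return sorted(preds, key=lambda p: (-p.confidence, p.pred_id))


def _candidate_key(crit: LocalizationCriterion, score: float,
                   pred: Prediction, ref: ReferenceObject) -> tuple:
    # maximize score; point-kind indicator ties break by center distance
    if crit.kind in POINT_KINDS:
        return (-score, center_distance(pred.box, ref.mask, crit.reference_center),
                ref.ref_id)
    return (-score, ref.ref_id)


def match_image(preds: Sequence[Prediction], refs: Sequence[ReferenceObject],
                crit: LocalizationCriterion) -> ImageMatching:
    """Greedy one-to-one assignment of predictions to references on one image."""
    matches: list[tuple[str, str]] = []
    unmatched_preds: list[str] = []
    open_refs = list(refs)
    for pred in _ordered(preds):
        best: Optional[ReferenceObject] = None
        best_key: Optional[tuple] = None
        for ref in open_refs:
            ps = pair_score(pred, ref, crit)
            if not ps.hit:
                continue
            key = _candidate_key(crit, ps.score, pred, ref)
            if best_key is None or key < best_key:
                best, best_key = ref, key
        if best is None:
            unmatched_preds.append(pred.pred_id)
        else:
            matches.append((pred.pred_id, best.ref_id))
            open_refs.remove(best)
    return ImageMatching(
        matches=matches,
        unmatched_preds=unmatched_preds,
        unmatched_refs=[r.ref_id for r in open_refs],
    )


def confusion_counts(ds: Dataset, crit: LocalizationCriterion,
                     confidence_cutoff: float = 0.5) -> ConfusionCounts:
    """Dataset-level TP/FP/FN at a confidence cutoff.

    Predictions with confidence >= cutoff are matched per image; matches are
    TP, surviving unmatched predictions FP, unmatched references FN. The
    cutoff is a reporting parameter, never an implicit default downstream:
    counting metrics are only interpretable alongside it.
    """
    if not (0.0 <= confidence_cutoff <= 1.0):
        raise UsageError(f"confidence cutoff {confidence_cutoff} outside [0, 1]")
    refs_by_img = ds.references_by_image()
    preds_by_img = ds.predictions_by_image()
    tp = fp = fn = 0
    for image_id in refs_by_img:
        kept = [p for p in preds_by_img[image_id]
                if p.confidence >= confidence_cutoff]
        m = match_image(kept, refs_by_img[image_id], crit)
        tp += len(m.matches)
        fp += len(m.unmatched_preds)
        fn += len(m.unmatched_refs)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)
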