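"""Object-level classification metrics and Average Precision.

Counting metrics (Sensitivity, PPV, F-beta) summarize a confusion matrix
obtained at a fixed confidence cutoff. Average Precision sweeps the cutoff
implicitly: predictions are pooled over all images of the evaluation scope
(micro pooling, the COCO convention), ranked by descending confidence, and
each rank prefix is re-matched to yield a precision–recall curve; AP is the
101-point interpolated mean of the precision envelope.

The greedy assignment is prefix-stable — matching the top-k predictions
equals restricting the full ranked matching to the first k — which lets the
whole curve be produced in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import Dataset
from .errors import UndefinedValueError, UsageError
from .matching import (
    OVERLAP_KINDS,
    POINT_KINDS,
    ConfusionCounts,
    LocalizationCriterion,
    confusion_counts,
    raw_score,
    score_is_hit,
)

__all__ = [
    "EvaluationCache",
    "MetricPanel",
    "PRCurve",
    "ap_range_mean",
    "ap_threshold_sweep",
    "average_precision",
    "f_beta",
    "metric_panel",
    "ppv",
    "pr_curve",
    "sensitivity",
]

RECALL_GRID = np.arange(101) / 100.0
COCO_RANGE = (0.5, 0.95)
DEFAULT_SWEEP_GRID = tuple(np.round(np.arange(1, 20) * 0.05, 2))


# ---------------------------------------------------------------------------
# counting metrics
# ---------------------------------------------------------------------------

def sensitivity(c: ConfusionCounts) -> float:
    """Recall at object level: TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise UndefinedValueError("sensitivity undefined: no references in scope")
    return c.tp / (c.tp + c.fn)


def ppv(c: ConfusionCounts) -> float:
    """Positive predictive value: TP / (TP + FP).

    Undefined (raises) when there are no predictions — callers report the
    value as absent rather than silently zero.
    """
    if c.tp + c.fp == 0:
        raise UndefinedValueError("PPV undefined: no predictions in scope")
    return c.tp / (c.tp + c.fp)


def f_beta(p: float, r: float, beta: float) -> float:
    """(1 + b^2) p r / (b^2 p + r); 0 by convention when p = r = 0."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise UsageError("precision and recall must lie in [0, 1]")
    if beta <= 0:
        raise UsageError("beta must be positive")
    if p + r == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * p * r / (b2 * p + r)


# ---------------------------------------------------------------------------
# ranked matching sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRCurve:
    """Per-rank (recall, precision) points of the descending-confidence sweep."""

    points: tuple[tuple[float, float], ...]
    n_references: int

    @property
    def recalls(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def precisions(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


class EvaluationCache:
    """Precomputed pair scores for repeated threshold sweeps on one dataset.

    Raw pair scores depend only on the criterion *kind*; thresholds are
    applied per sweep point. Caching them makes a 19-threshold sweep cost one
    geometry pass instead of nineteen.
    """

    def __init__(self, ds: Dataset) -> None:
        self.ds = ds
        self.n_references = len(ds.references)
        refs_by_img = ds.references_by_image()
        self._refs_by_img = refs_by_img
        self.ranked_preds = sorted(
            ds.predictions, key=lambda p: (-p.confidence, p.pred_id)
        )
        self._cand_cache: dict[tuple[str, str], list] = {}

    def candidates(self, kind: str, reference_center: str = "centroid"):
        """Per ranked prediction: list of (ref_id, score, tie_distance)."""
        key = (kind, reference_center)
        if key not in self._cand_cache:
            from .geometry import center_distance  # local to avoid cycle noise

            rows = []
            for pred in self.ranked_preds:
                cands = []
                for ref in self._refs_by_img.get(pred.image_id, []):
                    score = raw_score(pred, ref, kind, reference_center)
                    tie = (
                        center_distance(pred.box, ref.mask, reference_center)
                        if kind in POINT_KINDS
                        else 0.0
                    )
                    cands.append((ref.ref_id, score, tie))
                rows.append(cands)
            self._cand_cache[key] = rows
        return self._cand_cache[key]

    def ranked_outcomes(
        self, crit: LocalizationCriterion
    ) -> list[tuple[str, Optional[str]]]:
        """Greedy matching over the global confidence ranking.

        Returns, per ranked prediction, the ref_id it matched or ``None``
        (a false positive at that rank). Restricting to the first k rows
        reproduces per-image matching of the top-k predictions exactly.
        """
        rows = self.candidates(crit.kind, crit.reference_center)
        taken: set[str] = set()
        outcomes: list[tuple[str, Optional[str]]] = []
        for pred, cands in zip(self.ranked_preds, rows):
            best_id: Optional[str] = None
            best_key: Optional[tuple] = None
            for ref_id, score, tie in cands:
                if ref_id in taken or not score_is_hit(crit.kind, score, crit.threshold):
                    continue
                key = (-score, tie, ref_id)
                if best_key is None or key < best_key:
                    best_id, best_key = ref_id, key
            if best_id is not None:
                taken.add(best_id)
            outcomes.append((pred.pred_id, best_id))
        return outcomes


def pr_curve(ds: Dataset, crit: LocalizationCriterion,
             cache: Optional[EvaluationCache] = None) -> PRCurve:
    """Precision–recall curve from the pooled descending-confidence sweep."""
    cache = cache or EvaluationCache(ds)
    if cache.n_references == 0:
        raise UndefinedValueError("PR curve undefined: no references in scope")
    outcomes = cache.ranked_outcomes(crit)
    points = []
    tp = 0
    for k, (_, matched) in enumerate(outcomes, start=1):
        if matched is not None:
            tp += 1
        points.append((tp / cache.n_references, tp / k))
    return PRCurve(points=tuple(points), n_references=cache.n_references)


def _interpolated_ap(recalls: np.ndarray, precisions: np.ndarray,
                     interpolation: str) -> float:
    if len(recalls) == 0:
        return 0.0
    if interpolation == "coco101":
        total = 0.0
        for r in RECALL_GRID:
            sel = precisions[recalls >= r]
            if sel.size:
                total += float(sel.max())
        return total / len(RECALL_GRID)
    if interpolation == "all_points":
        # area under the right-continuous precision envelope
        env = np.maximum.accumulate(precisions[::-1])[::-1]
        r_prev = 0.0
        area = 0.0
        for r, p in zip(recalls, env):
            area += (r - r_prev) * p
            r_prev = r
        return float(area)
    raise UsageError(f"unknown interpolation {interpolation!r}")


def average_precision(ds: Dataset, crit: LocalizationCriterion,
                      cache: Optional[EvaluationCache] = None,
                      interpolation: str = "coco101") -> float:
    """101-point interpolated AP (COCO rule) for one localization criterion."""
    curve = pr_curve(ds, crit, cache=cache)
    return _interpolated_ap(curve.recalls, curve.precisions, interpolation)


def ap_threshold_sweep(ds: Dataset, crit_kind: str,
                       grid: Sequence[float] = DEFAULT_SWEEP_GRID,
                       cache: Optional[EvaluationCache] = None) -> dict[float, float]:
    """AP as a function of the IoU cutoff for one overlap-based kind."""
    if crit_kind not in OVERLAP_KINDS:
        raise UsageError(f"threshold sweep needs an overlap kind, got {crit_kind!r}")
    if len(grid) == 0:
        raise UsageError("empty threshold grid")
    cache = cache or EvaluationCache(ds)
    return {
        float(t): average_precision(ds, LocalizationCriterion(crit_kind, float(t)),
                                    cache=cache)
        for t in grid
    }


def ap_range_mean(ds: Dataset, crit_kind: str, lo: float, hi: float,
                  step: float = 0.05,
                  cache: Optional[EvaluationCache] = None) -> float:
    """Mean AP over thresholds lo, lo+step, ..., hi inclusive (e.g. AP@0.5:0.95)."""
    if not (0.0 <= lo <= hi <= 1.0):
        raise UsageError(f"bad threshold range [{lo}, {hi}]")
    n = int(round((hi - lo) / step)) + 1 if hi > lo else 1
    grid = [round(lo + i * step, 10) for i in range(n)]
    if grid[-1] > hi + 1e-9:
        grid = [t for t in grid if t <= hi + 1e-9]
    sweep = ap_threshold_sweep(ds, crit_kind, grid=grid, cache=cache)
    return float(np.mean(list(sweep.values())))


# ---------------------------------------------------------------------------
# combined panel
# ---------------------------------------------------------------------------

@dataclass
class MetricPanel:
    """The standard metric set at one criterion and confidence cutoff.

    ``ppv`` is None when the scope contains no predictions above the cutoff
    (undefined, reported absent). AP entries are keyed by threshold and by
    (lo, hi) range.
    """

    criterion: LocalizationCriterion
    confidence_cutoff: float
    counts: ConfusionCounts
    sensitivity: float
    ppv: Optional[float]
    f1: float
    f2: float
    ap_by_threshold: dict[float, float] = field(default_factory=dict)
    ap_range_means: dict[tuple[float, float], float] = field(default_factory=dict)


def metric_panel(ds: Dataset, crit: LocalizationCriterion,
                 confidence_cutoff: float = 0.5,
                 cache: Optional[EvaluationCache] = None) -> MetricPanel:
    """Sensitivity/PPV/F1/F2 at the cutoff plus AP@0.5, AP@0.75, AP@0.5:0.95.

    The AP entries use the panel criterion's kind when it is overlap-based
    (the usual configuration); for point or distance kinds a single AP under
    that criterion is reported instead, keyed by its own threshold.
    """
    cache = cache or EvaluationCache(ds)
    counts = confusion_counts(ds, crit, confidence_cutoff)
    sens = sensitivity(counts)
    try:
        prec: Optional[float] = ppv(counts)
    except UndefinedValueError:
        prec = None
    f1 = f_beta(prec, sens, 1.0) if prec is not None else 0.0
    f2 = f_beta(prec, sens, 2.0) if prec is not None else 0.0
    if crit.kind in OVERLAP_KINDS:
        ap_by_threshold = {
            t: average_precision(ds, LocalizationCriterion(crit.kind, t), cache=cache)
            for t in (0.5, 0.75)
        }
        ap_ranges = {
            COCO_RANGE: ap_range_mean(ds, crit.kind, *COCO_RANGE, cache=cache)
        }
    else:
        ap_by_threshold = {crit.threshold: average_precision(ds, crit, cache=cache)}
        ap_ranges = {}
    return MetricPanel(
        criterion=crit,
        confidence_cutoff=confidence_cutoff,
        counts=counts,
        sensitivity=sens,
        ppv=prec,
        f1=f1,
        f2=f2,
        ap_by_threshold=ap_by_threshold,
        ap_range_means=ap_ranges,
    )
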