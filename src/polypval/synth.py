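"""Seeded synthetic multi-center studies.

Generates the three layers a validation study needs — reference masks with a
center/patient/image hierarchy, detector-like box predictions, and binary
usefulness ratings — with the statistical structure the analyses assume:

* per-center image counts and polyp prevalence matching a configurable
  profile (the shipped default mirrors a six-center colonoscopy test set:
  256/276/457/227/208/88 frames at 98/89/99/64/99/94 % prevalence,
  1920x1080);
* a small/medium/large polyp-size mixture with areas drawn from truncated
  log-normals inside each class interval (classes defined at 1920x1080 and
  scaled with image area);
* convex elliptical masks as a proxy for protruded polyps and non-convex
  crescent masks as a proxy for flat polyps (crescents exercise the
  point-in-mask vs point-in-hull disagreement);
* predictions derived from the true bounding box by center jitter, log-normal
  rescaling, size-dependent misses and Poisson false positives, with
  confidence = clip(realized mask IoU + Gaussian noise, 0, 1).

Jitter is *absolute* in pixels by default: a fixed localization error costs
small polyps far more IoU than large ones, which is the mechanism that
produces the size effect the study pipeline measures. The ``"relative"``
mode scales jitter with object size and serves as the negative control under
which the size effect should vanish.

Everything is driven by a single named ``numpy`` generator per operation, so
a fixed seed yields byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import (
    Dataset,
    ImageRecord,
    Prediction,
    ReferenceObject,
    UsefulnessRating,
)
from .errors import GenerationError, UsageError
from .geometry import Box, RasterRegion, region_iou
from .matching import LocalizationCriterion, pair_score

__all__ = [
    "CenterProfile",
    "PerturbationModel",
    "RatingModel",
    "StudySpec",
    "default_study_spec",
    "generate_predictions",
    "generate_references",
    "generate_study",
    "simulate_ratings",
    "study_spec_from_dict",
    "study_spec_to_dict",
]

REFERENCE_RESOLUTION = (1920, 1080)
SIZE_CLASSES = ("small", "medium", "large")
# class intervals in px^2 at the reference resolution: small < 100^2,
# large > 200^2, medium the rest
SMALL_MAX_AREA = 100 ** 2
LARGE_MIN_AREA = 200 ** 2
_CLASS_INTERVALS = {
    "small": (40 ** 2, SMALL_MAX_AREA),
    "medium": (SMALL_MAX_AREA, LARGE_MIN_AREA),
    "large": (LARGE_MIN_AREA, 4 * LARGE_MIN_AREA),
}
# log-normal (median, sigma) of the target area per class, reference scale
_CLASS_LOGNORMAL = {
    "small": (5_000.0, 0.5),
    "medium": (20_000.0, 0.4),
    "large": (75_000.0, 0.4),
}
_TWO_POLYP_PROB = 0.05


@dataclass(frozen=True)
class CenterProfile:
    """Generative configuration of one validation center."""

    center_id: str
    n_images: int
    prevalence: float
    resolution: tuple[int, int] = REFERENCE_RESOLUTION
    size_mixture: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    shape_mixture: tuple[float, float] = (0.7, 0.3)  # (ellipse, crescent)
    n_patients: int = 0  # 0 -> one patient per ~4 images

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise UsageError(f"prevalence {self.prevalence} outside [0, 1]")
        for name, mix in (("size", self.size_mixture), ("shape", self.shape_mixture)):
            if any(w < 0 for w in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise UsageError(f"{name}_mixture must be non-negative and sum to 1")
        if self.n_images < 1:
            raise UsageError("n_images must be >= 1")

    @property
    def patients(self) -> int:
        return self.n_patients or max(1, self.n_images // 4)


@dataclass(frozen=True)
class PerturbationModel:
    """Detector stand-in: how predictions are derived from reference objects.

    ``miss_rate(area) = 1 / (1 + exp(miss_slope * (log area - log
    miss_midpoint_area)))`` — a logistic in log-area that misses small
    objects more often. The default midpoint (20^2 px at 1080p) means only
    speck-sized polyps are missed outright: modern detectors fail mostly by
    mislocalizing, not by producing no box at all, so the size effect in AP
    is carried by localization jitter rather than by recall ceilings.
    """

    miss_midpoint_area: float = 20.0 ** 2
    miss_slope: float = 2.0
    jitter_mode: str = "absolute"  # or "relative"
    center_jitter_sd: float = 25.0  # px, absolute mode
    relative_jitter_frac: float = 0.18  # * sqrt(area), relative mode
    scale_noise_sd: float = 0.10  # sd of log size factor
    fp_per_image: float = 0.1  # Poisson rate
    confidence_noise_sd: float = 0.1
    fp_confidence_beta: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        if self.jitter_mode not in ("absolute", "relative"):
            raise UsageError(f"unknown jitter_mode {self.jitter_mode!r}")
        for name in ("center_jitter_sd", "relative_jitter_frac", "scale_noise_sd",
                     "fp_per_image", "confidence_noise_sd"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be >= 0")

    def miss_rate(self, area_px: float) -> float:
        z = self.miss_slope * (math.log(area_px) - math.log(self.miss_midpoint_area))
        return 1.0 / (1.0 + math.exp(z))

    def jitter_sd(self, area_px: float) -> float:
        if self.jitter_mode == "absolute":
            return self.center_jitter_sd
        return self.relative_jitter_frac * math.sqrt(area_px)


@dataclass(frozen=True)
class RatingModel:
    """How synthetic clinician ratings are produced from predictions."""

    generating_criterion: LocalizationCriterion = LocalizationCriterion("mask_iou", 0.0)
    label_noise: float = 0.0
    rater_id: str = "synthetic_rater"

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise <= 1.0):
            raise UsageError(f"label_noise {self.label_noise} outside [0, 1]")


@dataclass(frozen=True)
class StudySpec:
    """Full generative configuration of a synthetic multi-center study."""

    centers: tuple[CenterProfile, ...]
    perturbation: PerturbationModel = PerturbationModel()
    rating: Optional[RatingModel] = None
    seed: int = 0


def default_study_spec(seed: int = 0, *,
                       perturbation: Optional[PerturbationModel] = None,
                       rating: Optional[RatingModel] = None) -> StudySpec:
    """The shipped six-center study: frame counts and prevalences of a
    published six-center colonoscopy test collection, at 1920x1080."""
    profile = [
        ("center_1", 256, 0.98),
        ("center_2", 276, 0.89),
        ("center_3", 457, 0.99),
        ("center_4", 227, 0.64),
        ("center_5", 208, 0.99),
        ("center_6", 88, 0.94),
    ]
    return StudySpec(
        centers=tuple(CenterProfile(c, n, phi) for c, n, phi in profile),
        perturbation=perturbation or PerturbationModel(),
        rating=rating,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# shape rasterization
# ---------------------------------------------------------------------------

def _rasterize_ellipse(area: float, rng: np.random.Generator
                       ) -> tuple[np.ndarray, str]:
    aspect = float(np.exp(np.clip(rng.normal(0.0, 0.3), -0.7, 0.7)))
    a = math.sqrt(area * aspect / math.pi)
    b = area / (math.pi * a)
    theta = rng.uniform(0.0, math.pi)
    return _ellipse_raster(a, b, theta), "protruded"


def _ellipse_raster(a: float, b: float, theta: float) -> np.ndarray:
    ext = int(math.ceil(max(a, b))) + 1
    ys, xs = np.mgrid[0 : 2 * ext, 0 : 2 * ext]
    dx = xs + 0.5 - ext
    dy = ys + 0.5 - ext
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return u * u + v * v <= 1.0


def _rasterize_crescent(area: float, rng: np.random.Generator
                        ) -> tuple[np.ndarray, str]:
    """Non-convex 'flat polyp' proxy: an ellipse with an elliptical bite.

    The bite removes ~40% of the outer area from one side, so the centroid
    can fall outside the mask and the convex hull strictly exceeds it.
    """
    bite_frac = rng.uniform(0.35, 0.5)
    outer_area = area / (1.0 - bite_frac)
    aspect = float(np.exp(np.clip(rng.normal(0.0, 0.2), -0.5, 0.5)))
    a = math.sqrt(outer_area * aspect / math.pi)
    b = outer_area / (math.pi * a)
    theta = rng.uniform(0.0, math.pi)
    outer = _ellipse_raster(a, b, theta)
    # bite: same orientation, carving into the middle of the shape so the
    # box center / centroid often falls in the concavity (the phenomenon
    # point-in-mask vs point-in-hull disagree on)
    bite_scale = rng.uniform(0.7, 0.9)
    phi = rng.uniform(0.0, 2 * math.pi)
    off = rng.uniform(0.55, 0.8) * max(a, b)
    ext = outer.shape[0] // 2
    ys, xs = np.mgrid[0 : outer.shape[0], 0 : outer.shape[1]]
    dx = xs + 0.5 - (ext + off * math.cos(phi))
    dy = ys + 0.5 - (ext + off * math.sin(phi))
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / (a * bite_scale)
    v = (-dx * st + dy * ct) / (b * bite_scale)
    bite = u * u + v * v <= 1.0
    crescent = outer & ~bite
    return (crescent if crescent.any() else outer), "flat"


def _sample_area(size_class: str, scale: float, rng: np.random.Generator) -> float:
    lo, hi = _CLASS_INTERVALS[size_class]
    # 15% interior margins absorb rasterization error near class boundaries
    lo_t, hi_t = lo * scale * 1.15, hi * scale * 0.85
    median, sigma = _CLASS_LOGNORMAL[size_class]
    mu = math.log(median * scale)
    for _ in range(1000):
        area = float(rng.lognormal(mu, sigma))
        if lo_t <= area <= hi_t:
            return area
    raise GenerationError(
        f"could not sample a {size_class} area inside [{lo_t:.0f}, {hi_t:.0f}]"
    )


def _class_of_area(area: float, scale: float) -> str:
    if area < SMALL_MAX_AREA * scale:
        return "small"
    if area > LARGE_MIN_AREA * scale:
        return "large"
    return "medium"


def _make_reference(ref_id: str, image: ImageRecord, size_class: str,
                    shape: str, rng: np.random.Generator) -> ReferenceObject:
    scale = (image.width * image.height) / (
        REFERENCE_RESOLUTION[0] * REFERENCE_RESOLUTION[1]
    )
    for _ in range(25):
        area = _sample_area(size_class, scale, rng)
        raster, polyp_type = (
            _rasterize_ellipse(area, rng) if shape == "ellipse"
            else _rasterize_crescent(area, rng)
        )
        region = RasterRegion("mask", 0, 0, raster).trimmed()
        h, w = region.raster.shape
        if w > image.width or h > image.height:
            raise GenerationError(
                f"{size_class} {shape} of extent {w}x{h} does not fit a "
                f"{image.width}x{image.height} image"
            )
        if _class_of_area(region.n_pixels, scale) != size_class:
            continue  # rasterization pushed the area across a class boundary
        x0 = int(rng.integers(0, image.width - w + 1))
        y0 = int(rng.integers(0, image.height - h + 1))
        return ReferenceObject(
            ref_id=ref_id,
            image_id=image.image_id,
            mask=RasterRegion("mask", x0, y0, region.raster),
            polyp_type=polyp_type,
        )
    raise GenerationError(
        f"could not realize a {size_class} {shape} inside its class interval"
    )


# ---------------------------------------------------------------------------
# generation operations
# ---------------------------------------------------------------------------

def generate_references(spec: StudySpec) -> Dataset:
    """Images and reference polyps for every center; no predictions yet."""
    rng = np.random.default_rng(spec.seed)
    images: list[ImageRecord] = []
    references: list[ReferenceObject] = []
    for profile in spec.centers:
        w, h = profile.resolution
        for i in range(profile.n_images):
            image = ImageRecord(
                image_id=f"{profile.center_id}_im{i:04d}",
                width=w,
                height=h,
                center_id=profile.center_id,
                patient_id=f"{profile.center_id}_pat{i % profile.patients:03d}",
            )
            images.append(image)
            if rng.random() >= profile.prevalence:
                continue
            n_polyps = 2 if rng.random() < _TWO_POLYP_PROB else 1
            for k in range(n_polyps):
                size_class = SIZE_CLASSES[
                    int(rng.choice(3, p=list(profile.size_mixture)))
                ]
                shape = ("ellipse", "crescent")[
                    int(rng.choice(2, p=list(profile.shape_mixture)))
                ]
                references.append(
                    _make_reference(f"{image.image_id}_ref{k}", image,
                                    size_class, shape, rng)
                )
    return Dataset(images=images, references=references)


def _clip_box_to_canvas(x0: int, y0: int, x1: int, y1: int,
                        width: int, height: int) -> Box:
    # keep at least one pixel of overlap with the canvas
    x0 = min(max(x0, -(x1 - x0) + 1), width - 1)
    x1 = max(x0 + 1, min(x1, width + (x1 - x0)))
    y0 = min(max(y0, -(y1 - y0) + 1), height - 1)
    y1 = max(y0 + 1, min(y1, height + (y1 - y0)))
    # clamp fully inside for cleanliness
    bw, bh = x1 - x0, y1 - y0
    x0 = min(max(x0, 0), width - 1)
    y0 = min(max(y0, 0), height - 1)
    x1 = min(max(x1, x0 + 1), width)
    y1 = min(max(y1, y0 + 1), height)
    return Box(x0, y0, x1, y1)


def generate_predictions(refs_ds: Dataset, model: PerturbationModel,
                         seed: int) -> Dataset:
    """Detector-like predictions for an existing reference dataset."""
    rng = np.random.default_rng(seed)
    refs_by_img = refs_ds.references_by_image()
    predictions: list[Prediction] = []
    for image in refs_ds.images:
        k = 0
        for ref in refs_by_img[image.image_id]:
            if rng.random() < model.miss_rate(ref.area_px):
                continue
            box = ref.box
            sd = model.jitter_sd(ref.area_px)
            dx, dy = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
            f = float(np.exp(rng.normal(0.0, model.scale_noise_sd))) \
                if model.scale_noise_sd > 0 else 1.0
            cx = (box.x0 + box.x1) / 2.0 + dx
            cy = (box.y0 + box.y1) / 2.0 + dy
            bw = max(1, int(round(box.width * f)))
            bh = max(1, int(round(box.height * f)))
            pbox = _clip_box_to_canvas(
                int(round(cx - bw / 2.0)), int(round(cy - bh / 2.0)),
                int(round(cx - bw / 2.0)) + bw, int(round(cy - bh / 2.0)) + bh,
                image.width, image.height,
            )
            iou = region_iou(pbox, ref.mask)
            conf = float(np.clip(iou + rng.normal(0.0, model.confidence_noise_sd),
                                 0.0, 1.0))
            predictions.append(
                Prediction(f"{image.image_id}_p{k}", image.image_id, pbox, conf)
            )
            k += 1
        for _ in range(int(rng.poisson(model.fp_per_image))):
            area = float(rng.lognormal(math.log(10_000.0), 0.8))
            aspect = float(np.exp(rng.normal(0.0, 0.3)))
            bw = max(2, min(int(round(math.sqrt(area * aspect))), image.width))
            bh = max(2, min(int(round(math.sqrt(area / aspect))), image.height))
            x0 = int(rng.integers(0, max(1, image.width - bw + 1)))
            y0 = int(rng.integers(0, max(1, image.height - bh + 1)))
            a, b = model.fp_confidence_beta
            conf = float(rng.beta(a, b))
            predictions.append(
                Prediction(f"{image.image_id}_p{k}", image.image_id,
                           Box(x0, y0, x0 + bw, y0 + bh), conf)
            )
            k += 1
    return Dataset(images=list(refs_ds.images), references=list(refs_ds.references),
                   predictions=predictions, ratings=refs_ds.ratings)


def simulate_ratings(ds: Dataset, model: RatingModel, seed: int) -> Dataset:
    """Rate every prediction useful/not_useful from the generating criterion,
    then flip each label independently with probability ``label_noise``."""
    if not ds.predictions:
        raise UsageError("cannot simulate ratings: dataset has no predictions")
    rng = np.random.default_rng(seed)
    refs_by_img = ds.references_by_image()
    ratings: list[UsefulnessRating] = []
    for pred in ds.predictions:
        hit = any(
            pair_score(pred, ref, model.generating_criterion).hit
            for ref in refs_by_img[pred.image_id]
        )
        if model.label_noise > 0 and rng.random() < model.label_noise:
            hit = not hit
        ratings.append(
            UsefulnessRating(pred.pred_id, "useful" if hit else "not_useful",
                             model.rater_id)
        )
    return Dataset(images=list(ds.images), references=list(ds.references),
                   predictions=list(ds.predictions), ratings=ratings)


def generate_study(spec: StudySpec) -> Dataset:
    """References, predictions and (optionally) ratings in one call.

    Sub-seeds are derived as seed, seed+1, seed+2 for the three stages so
    each stage can also be reproduced in isolation.
    """
    ds = generate_references(spec)
    ds = generate_predictions(ds, spec.perturbation, spec.seed + 1)
    if spec.rating is not None:
        ds = simulate_ratings(ds, spec.rating, spec.seed + 2)
    return ds


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def study_spec_to_dict(spec: StudySpec) -> dict:
    out = {
        "seed": spec.seed,
        "centers": [
            {
                "center_id": c.center_id,
                "n_images": c.n_images,
                "prevalence": c.prevalence,
                "resolution": list(c.resolution),
                "size_mixture": list(c.size_mixture),
                "shape_mixture": list(c.shape_mixture),
                "n_patients": c.n_patients,
            }
            for c in spec.centers
        ],
        "perturbation": {
            "miss_midpoint_area": spec.perturbation.miss_midpoint_area,
            "miss_slope": spec.perturbation.miss_slope,
            "jitter_mode": spec.perturbation.jitter_mode,
            "center_jitter_sd": spec.perturbation.center_jitter_sd,
            "relative_jitter_frac": spec.perturbation.relative_jitter_frac,
            "scale_noise_sd": spec.perturbation.scale_noise_sd,
            "fp_per_image": spec.perturbation.fp_per_image,
            "confidence_noise_sd": spec.perturbation.confidence_noise_sd,
            "fp_confidence_beta": list(spec.perturbation.fp_confidence_beta),
        },
    }
    if spec.rating is not None:
        out["rating"] = {
            "criterion_kind": spec.rating.generating_criterion.kind,
            "criterion_threshold": spec.rating.generating_criterion.threshold,
            "label_noise": spec.rating.label_noise,
            "rater_id": spec.rating.rater_id,
        }
    return out


def study_spec_from_dict(cfg: dict) -> StudySpec:
    try:
        centers = tuple(
            CenterProfile(
                center_id=c["center_id"],
                n_images=int(c["n_images"]),
                prevalence=float(c["prevalence"]),
                resolution=tuple(c.get("resolution", REFERENCE_RESOLUTION)),
                size_mixture=tuple(c.get("size_mixture", (1 / 3, 1 / 3, 1 / 3))),
                shape_mixture=tuple(c.get("shape_mixture", (0.7, 0.3))),
                n_patients=int(c.get("n_patients", 0)),
            )
            for c in cfg["centers"]
        )
    except (KeyError, TypeError) as exc:
        raise UsageError(f"malformed study config: {exc}") from exc
    pert_cfg = dict(cfg.get("perturbation", {}))
    if "fp_confidence_beta" in pert_cfg:
        pert_cfg["fp_confidence_beta"] = tuple(pert_cfg["fp_confidence_beta"])
    perturbation = PerturbationModel(**pert_cfg)
    rating = None
    if "rating" in cfg:
        r = cfg["rating"]
        rating = RatingModel(
            generating_criterion=LocalizationCriterion(
                r.get("criterion_kind", "mask_iou"),
                float(r.get("criterion_threshold", 0.0)),
            ),
            label_noise=float(r.get("label_noise", 0.0)),
            rater_id=r.get("rater_id", "synthetic_rater"),
        )
    return StudySpec(centers=centers, perturbation=perturbation, rating=rating,
                     seed=int(cfg.get("seed", 0)))
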