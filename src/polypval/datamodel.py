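"""In-memory data model: images, reference polyps, predictions, ratings.

A :class:`Dataset` is the unit every analysis consumes. Validation is eager:
constructing a dataset checks referential integrity (every reference,
prediction and rating resolves), id uniqueness, and the geometric invariants
of each record, so downstream modules can assume a consistent world.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ReferentialIntegrityError, UndefinedValueError, ValidationError
from .geometry import (
    Box,
    Point,
    RasterRegion,
    bounding_box,
    convex_hull_region,
    mask_centroid,
)

__all__ = [
    "Dataset",
    "ImageRecord",
    "Prediction",
    "ReferenceObject",
    "UsefulnessRating",
    "prevalence",
]

POLYP_TYPES = ("flat", "protruded")
RATING_VALUES = ("useful", "not_useful")


@dataclass(frozen=True)
class ImageRecord:
    """One single-frame endoscopic image with its provenance hierarchy."""

    image_id: str
    width: int
    height: int
    center_id: str
    patient_id: str

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError(f"image {self.image_id}: non-positive dimensions")


class ReferenceObject:
    """One annotated polyp: a binary mask plus derived geometry.

    The bounding box, convex hull and centroid are computed lazily and cached,
    since threshold sweeps evaluate them many times per object.
    """

    __slots__ = ("ref_id", "image_id", "mask", "polyp_type", "area_px",
                 "_bbox", "_hull", "_centroid")

    def __init__(
        self,
        ref_id: str,
        image_id: str,
        mask: RasterRegion,
        polyp_type: str,
    ) -> None:
        if polyp_type not in POLYP_TYPES:
            raise ValidationError(f"reference {ref_id}: bad polyp_type {polyp_type!r}")
        if mask.kind != "mask":
            raise ValidationError(f"reference {ref_id}: region kind must be 'mask'")
        self.ref_id = ref_id
        self.image_id = image_id
        self.mask = mask.trimmed()
        self.polyp_type = polyp_type
        self.area_px = self.mask.n_pixels
        self._bbox: Optional[Box] = None
        self._hull: Optional[RasterRegion] = None
        self._centroid: Optional[Point] = None

    @property
    def box(self) -> Box:
        if self._bbox is None:
            self._bbox = bounding_box(self.mask)
        return self._bbox

    @property
    def hull(self) -> RasterRegion:
        if self._hull is None:
            self._hull = convex_hull_region(self.mask)
        return self._hull

    @property
    def centroid(self) -> Point:
        if self._centroid is None:
            self._centroid = mask_centroid(self.mask)
        return self._centroid

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceObject):
            return NotImplemented
        return (
            self.ref_id == other.ref_id
            and self.image_id == other.image_id
            and self.polyp_type == other.polyp_type
            and self.mask == other.mask
        )

    def __repr__(self) -> str:
        return (
            f"ReferenceObject({self.ref_id!r}, image={self.image_id!r}, "
            f"type={self.polyp_type}, area={self.area_px})"
        )


@dataclass(frozen=True)
class Prediction:
    """One detector output: an axis-aligned box with a confidence score."""

    pred_id: str
    image_id: str
    box: Box
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"prediction {self.pred_id}: confidence {self.confidence} not in [0,1]"
            )


@dataclass(frozen=True)
class UsefulnessRating:
    """A clinician's binary judgment of one predicted box."""

    pred_id: str
    rating: str
    rater_id: str

    def __post_init__(self) -> None:
        if self.rating not in RATING_VALUES:
            raise ValidationError(
                f"rating for {self.pred_id}: value must be one of {RATING_VALUES}"
            )


@dataclass
class Dataset:
    """A validated multi-center collection of images, references, predictions.

    Ratings are optional; they are only consumed by the clinician-agreement
    analysis.
    """

    images: list[ImageRecord] = field(default_factory=list)
    references: list[ReferenceObject] = field(default_factory=list)
    predictions: list[Prediction] = field(default_factory=list)
    ratings: Optional[list[UsefulnessRating]] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- indexes -----------------------------------------------------------
    def image_by_id(self, image_id: str) -> ImageRecord:
        return self._image_index[image_id]

    @property
    def _image_index(self) -> dict[str, ImageRecord]:
        return {im.image_id: im for im in self.images}

    def references_by_image(self) -> dict[str, list[ReferenceObject]]:
        out: dict[str, list[ReferenceObject]] = {im.image_id: [] for im in self.images}
        for ref in self.references:
            out[ref.image_id].append(ref)
        return out

    def predictions_by_image(self) -> dict[str, list[Prediction]]:
        out: dict[str, list[Prediction]] = {im.image_id: [] for im in self.images}
        for pred in self.predictions:
            out[pred.image_id].append(pred)
        return out

    def center_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for im in self.images:
            seen.setdefault(im.center_id, None)
        return list(seen)

    def subset_center(self, center_id: str) -> "Dataset":
        """Restriction of the dataset to one validation center."""
        if center_id not in self.center_ids():
            raise ReferentialIntegrityError(f"unknown center {center_id!r}")
        keep = {im.image_id for im in self.images if im.center_id == center_id}
        pred_ids = {p.pred_id for p in self.predictions if p.image_id in keep}
        return Dataset(
            images=[im for im in self.images if im.image_id in keep],
            references=[r for r in self.references if r.image_id in keep],
            predictions=[p for p in self.predictions if p.image_id in keep],
            ratings=None
            if self.ratings is None
            else [r for r in self.ratings if r.pred_id in pred_ids],
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        images = self._image_index
        if len(images) != len(self.images):
            raise ValidationError("duplicate image_id in dataset")
        ref_ids: set[str] = set()
        for ref in self.references:
            if ref.ref_id in ref_ids:
                raise ValidationError(f"duplicate ref_id {ref.ref_id!r}")
            ref_ids.add(ref.ref_id)
            img = images.get(ref.image_id)
            if img is None:
                raise ReferentialIntegrityError(
                    f"reference {ref.ref_id!r} cites unknown image {ref.image_id!r}"
                )
            bb = ref.box
            if bb.x0 < 0 or bb.y0 < 0 or bb.x1 > img.width or bb.y1 > img.height:
                raise ValidationError(
                    f"reference {ref.ref_id!r}: mask leaves the "
                    f"{img.width}x{img.height} canvas"
                )
        pred_ids: set[str] = set()
        for pred in self.predictions:
            if pred.pred_id in pred_ids:
                raise ValidationError(f"duplicate pred_id {pred.pred_id!r}")
            pred_ids.add(pred.pred_id)
            img = images.get(pred.image_id)
            if img is None:
                raise ReferentialIntegrityError(
                    f"prediction {pred.pred_id!r} cites unknown image {pred.image_id!r}"
                )
            canvas = Box(0, 0, img.width, img.height)
            if not pred.box.intersects(canvas):
                raise ValidationError(
                    f"prediction {pred.pred_id!r}: box misses the image canvas"
                )
        if self.ratings is not None:
            rated: set[str] = set()
            for rating in self.ratings:
                if rating.pred_id not in pred_ids:
                    raise ReferentialIntegrityError(
                        f"rating cites unknown prediction {rating.pred_id!r}"
                    )
                if rating.pred_id in rated:
                    raise ValidationError(
                        f"prediction {rating.pred_id!r} rated more than once"
                    )
                rated.add(rating.pred_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.images == other.images
            and self.references == other.references
            and self.predictions == other.predictions
            and (self.ratings or []) == (other.ratings or [])
        )


def prevalence(ds: Dataset, center_id: Optional[str] = None) -> float:
    """Fraction of (center-filtered) images containing at least one polyp."""
    if center_id is not None:
        if center_id not in ds.center_ids():
            raise ReferentialIntegrityError(f"unknown center {center_id!r}")
        images = [im for im in ds.images if im.center_id == center_id]
    else:
        images = ds.images
    if not images:
        raise UndefinedValueError("prevalence undefined on zero images")
    with_polyp = {r.image_id for r in ds.references}
    return sum(im.image_id in with_polyp for im in images) / len(images)
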