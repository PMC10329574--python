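"""Reading and writing datasets.

Two on-disk dialects are supported, both rooted at a directory:

``coco_json``
    ``dataset.json`` — COCO-style ``images``/``annotations``/``categories``
    with the extra per-image fields ``center_id`` and ``patient_id`` and the
    per-annotation field ``polyp_type``. Segmentations may be polygons
    (flat ``[x1,y1,x2,y2,...]`` lists) or uncompressed run-length encodings
    (``{"size": [h, w], "counts": [...]}``, column-major, background first).
    ``predictions.json`` — COCO-results-style list of
    ``{"id", "image_id", "bbox": [x, y, w, h], "score"}``.
    ``ratings.csv`` — optional, header ``pred_id,rating,rater_id``.

``mask_png_dir``
    ``images.csv`` (image_id, width, height, center_id, patient_id),
    ``references.csv`` (ref_id, image_id, polyp_type, mask_path) pointing at
    binary mask PNGs, ``predictions.csv``
    (pred_id, image_id, x, y, width, height, confidence), optional
    ``ratings.csv``.

Writing is canonical — keys sorted, compact separators, records in a fixed
order, masks always emitted as RLE — so that the same dataset always
serializes to identical bytes and ``read_dataset`` inverts ``write_dataset``
exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import shapely
from PIL import Image

from .datamodel import (
    Dataset,
    ImageRecord,
    Prediction,
    ReferenceObject,
    UsefulnessRating,
)
from .errors import FormatError, ValidationError
from .geometry import Box, RasterRegion

__all__ = ["read_dataset", "write_dataset", "rle_encode", "rle_decode"]

DIALECTS = ("coco_json", "mask_png_dir")


# ---------------------------------------------------------------------------
# run-length encoding (COCO uncompressed convention: column-major flattening,
# alternating run lengths starting with background)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).ravel(order="F")
    if flat.size == 0:
        return []
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    starts = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(starts).tolist()
    if flat[0]:  # counts must start with a (possibly zero) background run
        counts = [0] + counts
    return [int(c) for c in counts]


def rle_decode(counts: Iterable[int], height: int, width: int) -> np.ndarray:
    counts = list(counts)
    total = sum(counts)
    if total != height * width:
        raise FormatError(
            f"RLE counts sum to {total}, expected {height * width} for "
            f"{height}x{width} mask"
        )
    flat = np.zeros(total, dtype=bool)
    pos = 0
    value = False
    for run in counts:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return flat.reshape((height, width), order="F")


def _rasterize_polygon(flat_coords: list[float], height: int, width: int) -> np.ndarray:
    if len(flat_coords) < 6 or len(flat_coords) % 2:
        raise FormatError("polygon segmentation needs >= 3 (x, y) pairs")
    pts = np.asarray(flat_coords, dtype=float).reshape(-1, 2)
    poly = shapely.Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    x0 = max(int(np.floor(pts[:, 0].min())), 0)
    y0 = max(int(np.floor(pts[:, 1].min())), 0)
    x1 = min(int(np.ceil(pts[:, 0].max())) + 1, width)
    y1 = min(int(np.ceil(pts[:, 1].max())) + 1, height)
    mask = np.zeros((height, width), dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    gx, gy = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
    inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    mask[y0:y1, x0:x1] = inside
    return mask


def _mask_to_region(ref_id: str, full_mask: np.ndarray) -> RasterRegion:
    if not full_mask.any():
        raise ValidationError(f"reference {ref_id!r} has an empty mask")
    return RasterRegion("mask", 0, 0, full_mask).trimmed()


def _full_canvas(ref: ReferenceObject, width: int, height: int) -> np.ndarray:
    full = np.zeros((height, width), dtype=bool)
    h, w = ref.mask.raster.shape
    full[ref.mask.y0 : ref.mask.y0 + h, ref.mask.x0 : ref.mask.x0 + w] = ref.mask.raster
    return full


def _box_from_xywh(x: float, y: float, w: float, h: float) -> Box:
    x0, y0 = int(round(x)), int(round(y))
    x1, y1 = int(round(x + w)), int(round(y + h))
    return Box(x0, y0, max(x1, x0 + 1), max(y1, y0 + 1))


# ---------------------------------------------------------------------------
# coco_json dialect
# ---------------------------------------------------------------------------

def _read_coco(path: Path) -> Dataset:
    ds_file = path / "dataset.json"
    if not ds_file.exists():
        raise FormatError(f"{ds_file} not found")
    try:
        payload = json.loads(ds_file.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{ds_file}: invalid JSON ({exc})") from exc

    images = []
    dims: dict[str, tuple[int, int]] = {}
    for rec in payload.get("images", []):
        for key in ("id", "width", "height"):
            if key not in rec:
                raise FormatError(f"image record missing {key!r}: {rec}")
        img = ImageRecord(
            image_id=str(rec["id"]),
            width=int(rec["width"]),
            height=int(rec["height"]),
            center_id=str(rec.get("center_id", "unknown")),
            patient_id=str(rec.get("patient_id", "unknown")),
        )
        images.append(img)
        dims[img.image_id] = (img.width, img.height)

    references = []
    for ann in payload.get("annotations", []):
        ref_id = str(ann.get("id"))
        image_id = str(ann.get("image_id"))
        seg = ann.get("segmentation")
        if image_id not in dims:
            # leave to Dataset.validate for a uniform referential error,
            # but we cannot rasterize without dimensions
            from .errors import ReferentialIntegrityError

            raise ReferentialIntegrityError(
                f"annotation {ref_id!r} cites unknown image {image_id!r}"
            )
        width, height = dims[image_id]
        if isinstance(seg, dict) and "counts" in seg:
            h, w = seg.get("size", (height, width))
            if (int(h), int(w)) != (height, width):
                raise FormatError(
                    f"annotation {ref_id!r}: RLE size {seg.get('size')} does not "
                    f"match image {height}x{width}"
                )
            full = rle_decode(seg["counts"], height, width)
        elif isinstance(seg, list) and seg and isinstance(seg[0], list):
            full = np.zeros((height, width), dtype=bool)
            for part in seg:
                full |= _rasterize_polygon(part, height, width)
        elif isinstance(seg, list):
            full = _rasterize_polygon(seg, height, width)
        else:
            raise FormatError(f"annotation {ref_id!r}: unsupported segmentation")
        references.append(
            ReferenceObject(
                ref_id=ref_id,
                image_id=image_id,
                mask=_mask_to_region(ref_id, full),
                polyp_type=str(ann.get("polyp_type", "protruded")),
            )
        )

    predictions = []
    pred_file = path / "predictions.json"
    if pred_file.exists():
        try:
            results = json.loads(pred_file.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{pred_file}: invalid JSON ({exc})") from exc
        for i, rec in enumerate(results):
            bbox = rec.get("bbox")
            if bbox is None or len(bbox) != 4:
                raise FormatError(f"prediction record {i}: missing 4-element bbox")
            predictions.append(
                Prediction(
                    pred_id=str(rec.get("id", f"pred_{i}")),
                    image_id=str(rec["image_id"]),
                    box=_box_from_xywh(*bbox),
                    confidence=float(rec["score"]),
                )
            )

    ratings = _read_ratings_csv(path / "ratings.csv")
    return Dataset(images=images, references=references, predictions=predictions,
                   ratings=ratings)


def _write_coco(ds: Dataset, path: Path) -> None:
    dims = {im.image_id: (im.width, im.height) for im in ds.images}
    payload = {
        "categories": [{"id": 1, "name": "polyp"}],
        "images": [
            {
                "center_id": im.center_id,
                "height": im.height,
                "id": im.image_id,
                "patient_id": im.patient_id,
                "width": im.width,
            }
            for im in ds.images
        ],
        "annotations": [
            {
                "area": ref.area_px,
                "bbox": [ref.box.x0, ref.box.y0, ref.box.width, ref.box.height],
                "category_id": 1,
                "id": ref.ref_id,
                "image_id": ref.image_id,
                "polyp_type": ref.polyp_type,
                "segmentation": {
                    "counts": rle_encode(_full_canvas(ref, *dims[ref.image_id])),
                    "size": [dims[ref.image_id][1], dims[ref.image_id][0]],
                },
            }
            for ref in ds.references
        ],
    }
    _dump_json(payload, path / "dataset.json")
    results = [
        {
            "bbox": [p.box.x0, p.box.y0, p.box.width, p.box.height],
            "id": p.pred_id,
            "image_id": p.image_id,
            "score": p.confidence,
        }
        for p in ds.predictions
    ]
    _dump_json(results, path / "predictions.json")
    if ds.ratings is not None:
        _write_ratings_csv(ds.ratings, path / "ratings.csv")


def _dump_json(obj, file: Path) -> None:
    file.write_text(
        json.dumps(obj, sort_keys=True, separators=(",", ":"), allow_nan=False) + "\n"
    )


# ---------------------------------------------------------------------------
# mask_png_dir dialect
# ---------------------------------------------------------------------------

def _read_mask_dir(path: Path) -> Dataset:
    img_file = path / "images.csv"
    if not img_file.exists():
        raise FormatError(f"{img_file} not found")
    images = []
    with img_file.open(newline="") as fh:
        for row in csv.DictReader(fh):
            try:
                images.append(
                    ImageRecord(
                        image_id=row["image_id"],
                        width=int(row["width"]),
                        height=int(row["height"]),
                        center_id=row["center_id"],
                        patient_id=row["patient_id"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"images.csv: bad row {row} ({exc})") from exc

    references = []
    ref_file = path / "references.csv"
    if ref_file.exists():
        with ref_file.open(newline="") as fh:
            for row in csv.DictReader(fh):
                mask_path = path / row["mask_path"]
                if not mask_path.exists():
                    raise FormatError(f"mask file {mask_path} not found")
                full = np.asarray(Image.open(mask_path)) > 0
                references.append(
                    ReferenceObject(
                        ref_id=row["ref_id"],
                        image_id=row["image_id"],
                        mask=_mask_to_region(row["ref_id"], full),
                        polyp_type=row["polyp_type"],
                    )
                )

    predictions = []
    pred_file = path / "predictions.csv"
    if pred_file.exists():
        with pred_file.open(newline="") as fh:
            for row in csv.DictReader(fh):
                x, y = int(row["x"]), int(row["y"])
                predictions.append(
                    Prediction(
                        pred_id=row["pred_id"],
                        image_id=row["image_id"],
                        box=Box(x, y, x + int(row["width"]), y + int(row["height"])),
                        confidence=float(row["confidence"]),
                    )
                )

    ratings = _read_ratings_csv(path / "ratings.csv")
    return Dataset(images=images, references=references, predictions=predictions,
                   ratings=ratings)


def _write_mask_dir(ds: Dataset, path: Path) -> None:
    dims = {im.image_id: (im.width, im.height) for im in ds.images}
    with (path / "images.csv").open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["image_id", "width", "height", "center_id", "patient_id"])
        for im in ds.images:
            w.writerow([im.image_id, im.width, im.height, im.center_id, im.patient_id])
    mask_dir = path / "masks"
    mask_dir.mkdir(exist_ok=True)
    with (path / "references.csv").open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["ref_id", "image_id", "polyp_type", "mask_path"])
        for ref in ds.references:
            rel = f"masks/{ref.ref_id}.png"
            full = _full_canvas(ref, *dims[ref.image_id])
            Image.fromarray(full.astype(np.uint8) * 255).save(path / rel)
            w.writerow([ref.ref_id, ref.image_id, ref.polyp_type, rel])
    with (path / "predictions.csv").open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["pred_id", "image_id", "x", "y", "width", "height", "confidence"])
        for p in ds.predictions:
            w.writerow(
                [p.pred_id, p.image_id, p.box.x0, p.box.y0, p.box.width,
                 p.box.height, repr(p.confidence)]
            )
    if ds.ratings is not None:
        _write_ratings_csv(ds.ratings, path / "ratings.csv")


# ---------------------------------------------------------------------------
# ratings CSV (shared by both dialects)
# ---------------------------------------------------------------------------

def _read_ratings_csv(file: Path) -> Optional[list[UsefulnessRating]]:
    if not file.exists():
        return None
    with file.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != {
            "pred_id", "rating", "rater_id",
        }:
            raise FormatError(
                "ratings.csv must have header pred_id,rating,rater_id "
                "(ratings attach to predictions, not images)"
            )
        return [
            UsefulnessRating(row["pred_id"], row["rating"], row["rater_id"])
            for row in reader
        ]


def _write_ratings_csv(ratings: list[UsefulnessRating], file: Path) -> None:
    with file.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["pred_id", "rating", "rater_id"])
        for r in ratings:
            w.writerow([r.pred_id, r.rating, r.rater_id])


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_dataset(path, dialect: str = "coco_json") -> Dataset:
    """Load and validate a dataset directory in the given dialect."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"dataset path {path} does not exist")
    if dialect == "coco_json":
        return _read_coco(path)
    if dialect == "mask_png_dir":
        return _read_mask_dir(path)
    raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_dataset(ds: Dataset, path, dialect: str = "coco_json") -> None:
    """Serialize a dataset canonically; ``read_dataset`` inverts this exactly."""
    ds.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if dialect == "coco_json":
        _write_coco(ds, path)
    elif dialect == "mask_png_dir":
        _write_mask_dir(ds, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
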