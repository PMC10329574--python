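"""Pixel-raster and box geometry.

Conventions (used consistently across the toolkit):

* Coordinates are 0-based pixel indices. A box is half-open,
  ``[x0, x1) x [y0, y1)``, with integer corners, so its area is exact integer
  arithmetic: ``(x1 - x0) * (y1 - y0)``.
* A mask pixel at row ``r``, column ``c`` occupies the unit square
  ``[c, c+1) x [r, r+1)`` in continuous coordinates; its center is
  ``(c + 0.5, r + 0.5)``.
* The convex hull of a mask is the hull of the union of its foreground unit
  squares (equivalently, of all pixel corners), rasterized by pixel-center
  inclusion with the boundary counting as inside. This guarantees the
  containment chain ``mask ⊆ hull ⊆ bounding box`` as pixel sets, even for
  degenerate (single-pixel, collinear) masks.
* Point membership is decided by the pixel containing the point (floor of
  both coordinates): a point on an exact pixel boundary belongs to the pixel
  to its lower-right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import shapely

from .errors import ValidationError

__all__ = [
    "Box",
    "Point",
    "RasterRegion",
    "bounding_box",
    "box_center",
    "box_iou",
    "box_region",
    "center_distance",
    "convex_hull_region",
    "mask_centroid",
    "point_in_region",
    "region_iou",
]


@dataclass(frozen=True)
class Point:
    """A real-valued position in pixel coordinates (may lie off-canvas)."""

    x: float
    y: float


@dataclass(frozen=True, order=True)
class Box:
    """Axis-aligned half-open pixel box ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValidationError(
                f"degenerate box [{self.x0},{self.x1})x[{self.y0},{self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersects(self, other: "Box") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass(frozen=True)
class RasterRegion:
    """A binary pixel set stored as a cropped raster plus a canvas offset.

    ``raster[r, c]`` refers to the canvas pixel ``(row = y0 + r, col = x0 + c)``.
    Storing masks cropped keeps a full multi-center study in memory at the
    cost of the polyp areas only, not the image canvases.
    """

    kind: str  # "mask" | "hull" | "box"
    x0: int
    y0: int
    raster: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        raster = np.ascontiguousarray(self.raster, dtype=bool)
        object.__setattr__(self, "raster", raster)
        if raster.ndim != 2 or not raster.any():
            raise ValidationError(f"{self.kind} region is empty or not 2-D")
        object.__setattr__(self, "_n_pixels", int(raster.sum()))

    @property
    def n_pixels(self) -> int:
        return self._n_pixels

    def pixel_is_set(self, col: int, row: int) -> bool:
        r, c = row - self.y0, col - self.x0
        h, w = self.raster.shape
        return 0 <= r < h and 0 <= c < w and bool(self.raster[r, c])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RasterRegion):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.x0 == other.x0
            and self.y0 == other.y0
            and self.raster.shape == other.raster.shape
            and bool(np.array_equal(self.raster, other.raster))
        )

    def trimmed(self) -> "RasterRegion":
        """Identical pixel set with the raster cropped to its tight extent."""
        rows = np.flatnonzero(self.raster.any(axis=1))
        cols = np.flatnonzero(self.raster.any(axis=0))
        return RasterRegion(
            self.kind,
            self.x0 + int(cols[0]),
            self.y0 + int(rows[0]),
            self.raster[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1],
        )


RegionLike = Union[Box, RasterRegion]


def bounding_box(region: RasterRegion) -> Box:
    """Minimal half-open box containing every foreground pixel."""
    rows = np.flatnonzero(region.raster.any(axis=1))
    cols = np.flatnonzero(region.raster.any(axis=0))
    return Box(
        x0=region.x0 + int(cols[0]),
        y0=region.y0 + int(rows[0]),
        x1=region.x0 + int(cols[-1]) + 1,
        y1=region.y0 + int(rows[-1]) + 1,
    )


def box_region(box: Box) -> RasterRegion:
    """The box as an explicit pixel set (used for raster cross-checks)."""
    return RasterRegion("box", box.x0, box.y0, np.ones((box.height, box.width), bool))


def convex_hull_region(mask: RasterRegion) -> RasterRegion:
    """Convex hull of the union of foreground unit squares, rasterized.

    The hull polygon is taken over all four corners of every foreground
    pixel; a pixel belongs to the hull raster iff its center lies inside the
    polygon or on its boundary. The result always contains the mask and is
    contained in its bounding box.
    """
    raster = mask.raster
    # the hull of all pixel corners equals the hull of the corners of
    # non-interior pixels (a 4-interior pixel cannot contribute an extreme
    # corner), which keeps the point set small for filled shapes
    core = np.zeros_like(raster)
    core[1:-1, 1:-1] = (
        raster[1:-1, 1:-1]
        & raster[:-2, 1:-1]
        & raster[2:, 1:-1]
        & raster[1:-1, :-2]
        & raster[1:-1, 2:]
    )
    rr, cc = np.nonzero(raster & ~core)
    xs = cc + mask.x0
    ys = rr + mask.y0
    corners = np.unique(
        np.concatenate(
            [
                np.stack([xs, ys], 1),
                np.stack([xs + 1, ys], 1),
                np.stack([xs, ys + 1], 1),
                np.stack([xs + 1, ys + 1], 1),
            ]
        ),
        axis=0,
    )
    hull = shapely.MultiPoint(corners).convex_hull
    bb = bounding_box(mask)
    gx, gy = np.meshgrid(
        np.arange(bb.x0, bb.x1) + 0.5, np.arange(bb.y0, bb.y1) + 0.5
    )
    if hull.geom_type == "Polygon":
        # scanline fill: hull vertices have integer coordinates and scanlines
        # run at half-integers, so a scanline never passes through a vertex or
        # horizontal edge — each row crosses exactly two edges of the convex
        # ring. The epsilon keeps centers lying exactly on a slanted edge
        # inside despite the division rounding (true clearances are >= 1/(2*dy)).
        verts = np.asarray(hull.exterior.coords)
        ex0, ey0 = verts[:-1, 0], verts[:-1, 1]
        ex1, ey1 = verts[1:, 0], verts[1:, 1]
        yc = np.arange(bb.y0, bb.y1) + 0.5
        crosses = (ey0[None, :] < yc[:, None]) != (ey1[None, :] < yc[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            tx = ex0 + (yc[:, None] - ey0) * (ex1 - ex0) / (ey1 - ey0)
        tx = np.where(crosses, tx, np.nan)
        with np.errstate(invalid="ignore"):
            xmin = np.nanmin(tx, axis=1)
            xmax = np.nanmax(tx, axis=1)
        xc = np.arange(bb.x0, bb.x1) + 0.5
        eps = 1e-9
        inside = (xc[None, :] >= xmin[:, None] - eps) & (
            xc[None, :] <= xmax[:, None] + eps
        )
    else:
        # degenerate (collinear/single-pixel) hull: defer to shapely;
        # intersects == covers for points, so the boundary stays inside
        inside = shapely.intersects_xy(hull, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return RasterRegion("hull", bb.x0, bb.y0, inside)


def mask_centroid(mask: RasterRegion) -> Point:
    """Mean of foreground pixel centers (may land on a background pixel)."""
    rr, cc = np.nonzero(mask.raster)
    return Point(
        x=float(cc.mean()) + mask.x0 + 0.5,
        y=float(rr.mean()) + mask.y0 + 0.5,
    )


def box_center(box: Box) -> Point:
    return Point((box.x0 + box.x1) / 2.0, (box.y0 + box.y1) / 2.0)


def box_iou(a: Box, b: Box) -> float:
    """Closed-form IoU of two half-open integer boxes."""
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def _intersection_pixels(a: RasterRegion, b: RasterRegion) -> int:
    x0 = max(a.x0, b.x0)
    y0 = max(a.y0, b.y0)
    x1 = min(a.x0 + a.raster.shape[1], b.x0 + b.raster.shape[1])
    y1 = min(a.y0 + a.raster.shape[0], b.y0 + b.raster.shape[0])
    if x0 >= x1 or y0 >= y1:
        return 0
    wa = a.raster[y0 - a.y0 : y1 - a.y0, x0 - a.x0 : x1 - a.x0]
    wb = b.raster[y0 - b.y0 : y1 - b.y0, x0 - b.x0 : x1 - b.x0]
    return int(np.count_nonzero(wa & wb))


def _box_mask_intersection(box: Box, region: RasterRegion) -> int:
    x0 = max(box.x0, region.x0)
    y0 = max(box.y0, region.y0)
    x1 = min(box.x1, region.x0 + region.raster.shape[1])
    y1 = min(box.y1, region.y0 + region.raster.shape[0])
    if x0 >= x1 or y0 >= y1:
        return 0
    win = region.raster[y0 - region.y0 : y1 - region.y0, x0 - region.x0 : x1 - region.x0]
    return int(np.count_nonzero(win))


def region_iou(a: RegionLike, b: RegionLike) -> float:
    """IoU of two pixel sets; box-box pairs use the closed rectangle form.

    The closed form and the rasterized computation agree exactly because
    boxes have integer corners on the pixel grid.
    """
    if isinstance(a, Box) and isinstance(b, Box):
        return box_iou(a, b)
    if isinstance(a, Box):
        inter = _box_mask_intersection(a, b)
        union = a.area + b.n_pixels - inter
    elif isinstance(b, Box):
        inter = _box_mask_intersection(b, a)
        union = b.area + a.n_pixels - inter
    else:
        inter = _intersection_pixels(a, b)
        union = a.n_pixels + b.n_pixels - inter
    return inter / union if union else 0.0


def point_in_region(p: Point, r: RegionLike) -> bool:
    """True iff the pixel containing ``p`` is foreground in ``r``."""
    col = math.floor(p.x)
    row = math.floor(p.y)
    if isinstance(r, Box):
        return r.x0 <= col < r.x1 and r.y0 <= row < r.y1
    return r.pixel_is_set(col, row)


def center_distance(
    pred_box: Box, ref_mask: RasterRegion, reference_center: str = "centroid"
) -> float:
    """Euclidean distance between the prediction center and the reference center.

    The reference center defaults to the mask centroid (robust to bounding-box
    slack around elongated or crescent-shaped polyps); ``"box_center"``
    switches to the center of the reference bounding box.
    """
    p = box_center(pred_box)
    if reference_center == "centroid":
        q = mask_centroid(ref_mask)
    elif reference_center == "box_center":
        q = box_center(bounding_box(ref_mask))
    else:
        raise ValidationError(f"unknown reference_center {reference_center!r}")
    return math.hypot(p.x - q.x, p.y - q.y)
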