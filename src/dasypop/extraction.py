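"""Object-based building extraction.

An index raster (MBI or PanTex) is thresholded and split into 8-connected
objects; each object is then screened by a conjunction of feature rules
(index level, brightness, NDVI, elongation, rectangularity, shape
complexity), small interior holes are closed, and finally residential
objects are isolated with point-of-interest (POI) ancillary data.

The segmentation provider is deliberately simple and pluggable: any
labelled image can be fed to :func:`objects_from_labels` to reuse the rule
engine on top of a different segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .scene import IndexRaster, MultispectralScene, compute_brightness, compute_ndvi

__all__ = [
    "SegmentObject",
    "ClassificationRules",
    "POIRecord",
    "POI_CATEGORIES",
    "segment",
    "objects_from_labels",
    "rectangular_fit",
    "shape_index",
    "length_width_ratio",
    "perimeter_pixels",
    "classify_buildings",
    "fill_holes",
    "refine_residential",
    "sample_validation_points",
]

POI_CATEGORIES = ("public_service", "financial", "commercial", "entertainment", "residential")

EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SegmentObject:
    """One connected segmentation object with its decision features.

    ``rows``/``cols`` index the object's pixels; features are filled by
    :func:`objects_from_labels`.  ``height_m`` (BH) and population are
    attached by later stages.
    """

    id: int
    rows: np.ndarray
    cols: np.ndarray
    pixel_size: float
    features: dict = field(default_factory=dict)
    is_building: bool = False
    zone_id: int | None = None
    height_m: float | None = None
    population: float | None = None

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    @property
    def area_m2(self) -> float:
        return self.n_pixels * self.pixel_size**2

    @property
    def centroid_rc(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass(frozen=True)
class ClassificationRules:
    """Conjunctive screening thresholds for building objects.

    Defaults are the published rule set: MBI >= 6 (or PanTex >= 1.45),
    brightness >= 136, NDVI < 0.1, length/width in [1.5, 4.5],
    rectangular fit >= 0.6, shape index <= 2.6.
    """

    index_kind: str = "MBI"
    index_min: float = 6.0
    brightness_min: float = 136.0
    ndvi_max: float = 0.1
    lw_ratio_min: float = 1.5
    lw_ratio_max: float = 4.5
    rect_fit_min: float = 0.6
    shape_index_max: float = 2.6

    def __post_init__(self) -> None:
        if self.lw_ratio_min > self.lw_ratio_max:
            raise ValueError("lw_ratio bounds out of order")

    @classmethod
    def for_pantex(cls, **kw) -> "ClassificationRules":
        kw.setdefault("index_kind", "PANTEX")
        kw.setdefault("index_min", 1.45)
        return cls(**kw)


@dataclass(frozen=True)
class POIRecord:
    x: float
    y: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in POI_CATEGORIES:
            raise ValueError(f"unknown POI category {self.category!r}")


# ---------------------------------------------------------------------------
# per-object geometry features

def perimeter_pixels(mask: np.ndarray) -> float:
    """Exposed pixel-edge length of a binary object, in pixel units."""
    m = np.asarray(mask, dtype=bool)
    n = int(m.sum())
    horiz = int((m[:, 1:] & m[:, :-1]).sum())
    vert = int((m[1:, :] & m[:-1, :]).sum())
    return float(4 * n - 2 * (horiz + vert))


def _corner_points(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """The 4 corner coordinates (col, row) of every pixel square."""
    r = rows[:, None] + np.array([-0.5, -0.5, 0.5, 0.5])
    c = cols[:, None] + np.array([-0.5, 0.5, -0.5, 0.5])
    return np.column_stack([c.ravel(), r.ravel()])


def _min_rotated_rect(rows: np.ndarray, cols: np.ndarray):
    pts = MultiPoint(_corner_points(rows, cols))
    return pts.convex_hull.minimum_rotated_rectangle


def _rect_sides(rect) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(long, short, unit long axis, centre) of a shapely rectangle."""
    xy = np.asarray(rect.exterior.coords)[:4]
    e1, e2 = xy[1] - xy[0], xy[2] - xy[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    centre = xy[:4].mean(axis=0)
    if l1 >= l2:
        return l1, l2, e1 / max(l1, 1e-12), centre
    return l2, l1, e2 / max(l2, 1e-12), centre


def length_width_ratio(obj: SegmentObject) -> float:
    """Elongation: long over short side of the minimum-area oriented box."""
    rect = _min_rotated_rect(obj.rows, obj.cols)
    if rect.geom_type != "Polygon":  # degenerate single point cannot occur (corners)
        return 1.0
    long_s, short_s, _, _ = _rect_sides(rect)
    return float(long_s / max(short_s, 1e-12))


def rectangular_fit(obj: SegmentObject) -> float:
    """Fraction of the object's pixels inside an equal-area rectangle.

    The comparison rectangle keeps the orientation and aspect ratio of the
    object's minimum-area oriented bounding box, is centred on the pixel
    centroid, and is scaled so its area equals the object's pixel area.
    """
    rect = _min_rotated_rect(obj.rows, obj.cols)
    long_s, short_s, axis, _ = _rect_sides(rect)
    area = float(obj.n_pixels)
    scale = np.sqrt(area / max(long_s * short_s, 1e-12))
    hl, hs = long_s * scale / 2.0, short_s * scale / 2.0
    cx, cy = float(obj.cols.mean()), float(obj.rows.mean())
    ux, uy = axis
    vx, vy = -uy, ux
    px = obj.cols - cx
    py = obj.rows - cy
    along = px * ux + py * uy
    across = px * vx + py * vy
    eps = 1e-9
    inside = (np.abs(along) <= hl + eps) & (np.abs(across) <= hs + eps)
    return float(inside.sum() / area)


def shape_index(obj: SegmentObject) -> float:
    """Boundary complexity: perimeter / (4 sqrt(area)), in pixel units.

    Normalised so a solid square scores exactly 1; compact near-rectangular
    objects stay low while ragged or branched objects grow without bound.
    """
    shp = (int(obj.rows.max()) + 1, int(obj.cols.max()) + 1)
    off_r, off_c = int(obj.rows.min()), int(obj.cols.min())
    m = np.zeros((shp[0] - off_r, shp[1] - off_c), dtype=bool)
    m[obj.rows - off_r, obj.cols - off_c] = True
    return perimeter_pixels(m) / (4.0 * np.sqrt(obj.n_pixels))


# ---------------------------------------------------------------------------
# segmentation and rules

def objects_from_labels(
    labels: np.ndarray,
    scene: MultispectralScene,
    index: IndexRaster,
    ndvi: np.ndarray | None = None,
    brightness: np.ndarray | None = None,
) -> list[SegmentObject]:
    """Build :class:`SegmentObject` features from any labelled image (0 = background)."""
    ndvi = compute_ndvi(scene).values if ndvi is None else ndvi
    brightness = compute_brightness(scene).values if brightness is None else brightness
    objs: list[SegmentObject] = []
    for oid in range(1, int(labels.max()) + 1):
        rows, cols = np.nonzero(labels == oid)
        if len(rows) == 0:
            continue
        obj = SegmentObject(id=oid, rows=rows, cols=cols, pixel_size=scene.pixel_size)
        obj.features = {
            "index_mean": float(index.values[rows, cols].mean()),
            "brightness_mean": float(brightness[rows, cols].mean()),
            "ndvi_mean": float(ndvi[rows, cols].mean()),
            "lw_ratio": length_width_ratio(obj),
            "rect_fit": rectangular_fit(obj),
            "shape_index": shape_index(obj),
        }
        objs.append(obj)
    return objs


def segment(
    scene: MultispectralScene,
    index: IndexRaster,
    threshold: float,
    min_pixels: int = 1,
) -> list[SegmentObject]:
    """Threshold an index raster and split the support into 8-connected objects.

    Stands in for proprietary multiresolution segmentation: the decision
    logic downstream only needs labelled objects with features.
    """
    if index.values.shape != scene.shape:
        raise ValueError("index raster not co-registered with scene")
    mask = index.values >= threshold
    labels, _ = ndimage.label(mask, structure=EIGHT)
    objs = objects_from_labels(labels, scene, index)
    return [o for o in objs if o.n_pixels >= min_pixels]


def classify_buildings(objects: Sequence[SegmentObject], rules: ClassificationRules) -> list[SegmentObject]:
    """Label each object as building iff every rule passes; returns the same objects."""
    for obj in objects:
        f = obj.features
        obj.is_building = (
            f["index_mean"] >= rules.index_min
            and f["brightness_mean"] >= rules.brightness_min
            and f["ndvi_mean"] < rules.ndvi_max
            and rules.lw_ratio_min <= f["lw_ratio"] <= rules.lw_ratio_max
            and f["rect_fit"] >= rules.rect_fit_min
            and f["shape_index"] <= rules.shape_index_max
        )
    return list(objects)


def fill_holes(mask: np.ndarray, box: int = 5) -> np.ndarray:
    """Close interior holes no larger than ``box`` x ``box`` pixels.

    Holes larger than the box in either dimension are kept open; filling
    never removes foreground, so objects can only grow, and filling an
    interior hole cannot connect two distinct objects.
    """
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    holes = filled & ~mask
    hole_labels, n = ndimage.label(holes, structure=EIGHT)
    out = mask.copy()
    for sl_idx, sl in enumerate(ndimage.find_objects(hole_labels), start=1):
        if sl is None:
            continue
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if h <= box and w <= box:
            out[sl] |= hole_labels[sl] == sl_idx
    return out


def refine_residential(
    buildings: Sequence[SegmentObject],
    pois: Sequence[POIRecord],
    radius_m: float,
    scene: MultispectralScene,
) -> list[SegmentObject]:
    """Keep a building iff its nearest POI within ``radius_m`` is residential."""
    buildings = [b for b in buildings if b.is_building]
    if not pois:
        warnings.warn("no POIs supplied: every building dropped by residential refinement")
        return []
    tree = cKDTree([(p.x, p.y) for p in pois])
    kept = []
    for b in buildings:
        r, c = b.centroid_rc
        x, y = scene.pixel_to_world(np.array([r]), np.array([c]))
        dist, idx = tree.query([x[0], y[0]])
        if dist <= radius_m and pois[int(idx)].category == "residential":
            kept.append(b)
    return kept


def sample_validation_points(
    building_mask: np.ndarray,
    n_points: int,
    seed: int,
    building_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified random validation points: (rows, cols, is_building_truth).

    Mimics accuracy-assessment practice of drawing a fixed point sample
    stratified between building and non-building strata.
    """
    rng = np.random.default_rng(seed)
    rows_b, cols_b = np.nonzero(building_mask)
    rows_n, cols_n = np.nonzero(~building_mask)
    n_b = min(int(round(n_points * building_fraction)), len(rows_b))
    n_n = min(n_points - n_b, len(rows_n))
    ib = rng.choice(len(rows_b), size=n_b, replace=False) if n_b else np.array([], dtype=int)
    inn = rng.choice(len(rows_n), size=n_n, replace=False) if n_n else np.array([], dtype=int)
    rows = np.concatenate([rows_b[ib], rows_n[inn]])
    cols = np.concatenate([cols_b[ib], cols_n[inn]])
    truth = np.concatenate([np.ones(n_b, dtype=bool), np.zeros(n_n, dtype=bool)])
    return rows, cols, truth
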