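"""Shadow extraction, shadow-length measurement, and building height retrieval.

Two shadow routes are provided: the morphological shadow index (MSI, dark
counterpart of the MBI) and a colour-invariant route (c3 channel followed
by a 3x3 local-variance texture filter).  Either raster is binarised with a
maximum between-class variance (Otsu) threshold, cleaned of vegetation and
water with NDVI/NDWI, and cleaned of speckle and roads by connected-
component area and elongation rules.

Heights follow from shadow geometry: for solar altitude β a shadow of
ground length L corresponds to building height H = L·tan β.  L is measured
by scan lines through each shadow component parallel to the sun-shadow
axis, one line per pixel of cross-section; the per-line intersection
lengths are aggregated (median by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .extraction import EIGHT, SegmentObject, length_width_ratio
from .scene import (
    IndexRaster,
    MultispectralScene,
    SolarGeometry,
    c3_index,
    compute_ndvi,
    compute_ndwi,
    shadow_direction_rowcol,
)

__all__ = [
    "ShadowConfig",
    "ShadowComponent",
    "mbcv_threshold",
    "shadow_mask",
    "component_filter",
    "local_variance",
    "ciit_shadow",
    "shadow_length",
    "building_height",
    "shadow_components",
    "assign_heights",
    "height_error_table",
    "HEIGHT_ERROR_BIN_EDGES",
]

#: 2.5 m absolute-error bins used for height validation reports.
HEIGHT_ERROR_BIN_EDGES = (0.0, 2.5, 5.0, 7.5, 10.0, 12.5, math.inf)


@dataclass(frozen=True)
class ShadowConfig:
    ndvi_max: float = 0.1
    ndwi_max: float = 0.3
    min_area_m2: float = 30.0
    max_lw_ratio: float = 15.0
    aggregator: str = "median"  # of per-scan-line lengths: median | mean | max

    def __post_init__(self) -> None:
        if self.aggregator not in ("median", "mean", "max"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")


@dataclass
class ShadowComponent:
    """A connected shadow region with its measured representative length L."""

    id: int
    rows: np.ndarray
    cols: np.ndarray
    pixel_size: float
    line_lengths_m: np.ndarray | None = None
    length_m: float | None = None
    anchor_rc: tuple[float, float] | None = None

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    @property
    def area_m2(self) -> float:
        return self.n_pixels * self.pixel_size**2


def mbcv_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Maximum between-class-variance (Otsu) threshold of a 1-D sample.

    The sample is histogrammed into ``n_bins`` equal-width bins over its
    range; every bin boundary is scanned as a candidate threshold and the
    one maximising the between-class variance is returned (ties resolved by
    the mean of the maximising candidates).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or v.min() == v.max():
        raise ValueError("between-class variance needs at least two distinct values")
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = hist / hist.sum()
    centres = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)[:-1]                    # class weight below threshold k (bins 0..k)
    w1 = 1.0 - w0
    mu_cum = np.cumsum(p * centres)[:-1]
    mu_total = float((p * centres).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv = np.nan_to_num(bcv, nan=-1.0)
    # ties resolved by the mean of maximising candidates; relative tolerance
    # absorbs float jitter between algebraically identical partitions
    best = np.flatnonzero(bcv >= bcv.max() * (1.0 - 1e-9))
    # threshold between bin k and k+1
    return float(np.mean(edges[best + 1]))


def shadow_mask(
    index: IndexRaster,
    ndvi: np.ndarray,
    ndwi: np.ndarray,
    cfg: ShadowConfig | None = None,
) -> np.ndarray:
    """Binarise a shadow index at the MBCV threshold, then drop vegetation/water."""
    cfg = cfg or ShadowConfig()
    thr = mbcv_threshold(index.values)
    mask = index.values >= thr
    mask &= ~(ndvi > cfg.ndvi_max)
    mask &= ~(ndwi > cfg.ndwi_max)
    return mask


def component_filter(
    mask: np.ndarray,
    min_area_m2: float,
    max_lw_ratio: float,
    pixel_size: float,
) -> list[ShadowComponent]:
    """Connected-component cleanup: drop speckles (small area) and roads (elongated)."""
    labels, n = ndimage.label(mask, structure=EIGHT)
    comps: list[ShadowComponent] = []
    for cid in range(1, n + 1):
        rows, cols = np.nonzero(labels == cid)
        comp = ShadowComponent(id=cid, rows=rows, cols=cols, pixel_size=pixel_size)
        if comp.area_m2 < min_area_m2:
            continue
        probe = SegmentObject(id=cid, rows=rows, cols=cols, pixel_size=pixel_size)
        if length_width_ratio(probe) > max_lw_ratio:
            continue
        comps.append(comp)
    return comps


def local_variance(values: np.ndarray, size: int = 3) -> np.ndarray:
    """Local variance in a size x size neighbourhood (reflective borders)."""
    v = np.asarray(values, dtype=np.float64)
    mean = ndimage.uniform_filter(v, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(v * v, size=size, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


def ciit_shadow(scene: MultispectralScene, cfg: ShadowConfig | None = None) -> np.ndarray:
    """Colour-invariant shadow route: c3 -> 3x3 local variance -> MBCV -> cleanup mask.

    The variance image highlights shadow boundaries; thresholding it and
    applying the same NDVI/NDWI filter as the morphological route yields the
    candidate shadow mask (components still need :func:`component_filter`).
    """
    cfg = cfg or ShadowConfig()
    c3 = c3_index(scene)
    var = local_variance(c3.values, size=3)
    if var.min() == var.max():
        return np.zeros(scene.shape, dtype=bool)
    index = IndexRaster(var, "C3", provenance={"filter": "local_variance_3x3"})
    return shadow_mask(index, compute_ndvi(scene).values, compute_ndwi(scene).values, cfg)


def shadow_length(
    comp: ShadowComponent,
    solar: SolarGeometry,
    pixel_size: float,
    aggregator: str = "median",
) -> float:
    """Representative shadow length L (m) along the sun-shadow axis.

    Pixels are projected onto the axis perpendicular to the shadow
    direction and grouped into unit-pixel scan lines; each line's
    intersection length is its pixel count times the pixel size, and L
    aggregates the per-line lengths.  Also records the per-line lengths and
    the anchor pixel (sun-side end) on the component.
    """
    if comp.n_pixels == 0:
        raise ValueError("empty shadow component")
    dr, dc = shadow_direction_rowcol(solar)
    # perpendicular (cross-section) coordinate in pixel units
    perp = comp.rows * (-dc) + comp.cols * dr
    along = comp.rows * dr + comp.cols * dc
    bins = np.floor(perp - perp.min() + 0.5).astype(int)
    counts = np.bincount(bins)
    lengths = counts[counts > 0] * pixel_size
    agg = {"median": np.median, "mean": np.mean, "max": np.max}[aggregator]
    comp.line_lengths_m = lengths.astype(float)
    comp.length_m = float(agg(lengths))
    # sun-side anchor: pixel with minimal projection on the shadow direction
    i = int(np.argmin(along))
    comp.anchor_rc = (float(comp.rows[i]), float(comp.cols[i]))
    return comp.length_m


def building_height(length_m: float, solar: SolarGeometry) -> float:
    """H = L tan(β) for solar altitude β in (0, 90) degrees."""
    if length_m < 0:
        raise ValueError("shadow length must be non-negative")
    return length_m * solar.tan_altitude


def shadow_components(
    scene: MultispectralScene,
    index: IndexRaster,
    cfg: ShadowConfig | None = None,
) -> list[ShadowComponent]:
    """Full shadow stage: threshold + spectral filter + component cleanup + lengths."""
    cfg = cfg or ShadowConfig()
    mask = shadow_mask(index, compute_ndvi(scene).values, compute_ndwi(scene).values, cfg)
    comps = component_filter(mask, cfg.min_area_m2, cfg.max_lw_ratio, scene.pixel_size)
    for comp in comps:
        shadow_length(comp, scene.solar, scene.pixel_size, cfg.aggregator)
    return comps


def assign_heights(
    buildings: list[SegmentObject],
    components: list[ShadowComponent],
    solar: SolarGeometry,
    pixel_size: float,
    idw_power: float = 2.0,
    max_distance_m: float | None = None,
    default_height_m: float = 10.0,
) -> list[SegmentObject]:
    """Transfer shadow-derived heights onto building objects.

    Each shadow contributes one height sample H = L tan β anchored at its
    sun-side pixel; building centroids receive the inverse-distance-weighted
    (power ``idw_power``) mean of the samples.  A centroid exactly on a
    sample takes that sample's height.  With ``max_distance_m`` set,
    buildings with no sample in range fall back to the median sample height;
    with no shadows at all, every building gets ``default_height_m``.
    """
    if not components:
        warnings.warn("no shadow components: assigning default height to all buildings")
        for b in buildings:
            b.height_m = default_height_m
        return buildings
    samples = []
    for comp in components:
        if comp.length_m is None:
            shadow_length(comp, solar, pixel_size)
        samples.append((comp.anchor_rc[0], comp.anchor_rc[1], building_height(comp.length_m, solar)))
    srows = np.array([s[0] for s in samples])
    scols = np.array([s[1] for s in samples])
    sh = np.array([s[2] for s in samples])
    fallback = float(np.median(sh))
    for b in buildings:
        r, c = b.centroid_rc
        d = np.hypot(srows - r, scols - c) * pixel_size
        if max_distance_m is not None:
            in_range = d <= max_distance_m
        else:
            in_range = np.ones_like(d, dtype=bool)
        if not in_range.any():
            b.height_m = fallback
            continue
        d_in, h_in = d[in_range], sh[in_range]
        if d_in.min() < 1e-9:
            b.height_m = float(h_in[np.argmin(d_in)])
            continue
        w = 1.0 / d_in**idw_power
        b.height_m = float((w * h_in).sum() / w.sum())
    return buildings


def height_error_table(
    estimated: np.ndarray,
    reference: np.ndarray,
    bin_edges: tuple[float, ...] = HEIGHT_ERROR_BIN_EDGES,
) -> dict:
    """Absolute-error distribution in 2.5 m bins plus RMSE.

    Returns counts and percentages per bin (ascending magnitude) and the
    root-mean-square error over the validation points.
    """
    est = np.asarray(estimated, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if est.shape != ref.shape:
        raise ValueError("estimated and reference must align")
    err = np.abs(est - ref)
    counts, _ = np.histogram(err, bins=np.asarray(bin_edges))
    pct = counts / max(len(err), 1) * 100.0
    return {
        "bin_edges": tuple(bin_edges),
        "counts": counts.astype(int),
        "percentages": pct,
        "rmse": float(np.sqrt(np.mean((est - ref) ** 2))) if len(err) else float("nan"),
        "n": int(len(err)),
    }
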