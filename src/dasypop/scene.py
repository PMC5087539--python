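"""Core raster data model: multispectral band stacks and derived spectral indices.

The working unit for the whole pipeline is a :class:`MultispectralScene`
holding co-registered blue/green/red/NIR bands (plus an optional panchromatic
band) on one grid, together with the pixel size and the solar geometry at
acquisition time.  Digital numbers are normalised to an 8-bit-like 0-255
range on load so that published thresholds on brightness and gray levels
stay meaningful.

Grid convention (shared by every module): arrays are indexed ``(row, col)``
with row 0 at the north edge and columns increasing eastward.  Solar azimuth
is measured clockwise from grid north, so a shadow cast away from the sun
travels along azimuth + 180°.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "SolarGeometry",
    "MultispectralScene",
    "IndexKind",
    "IndexRaster",
    "compute_brightness",
    "compute_ndvi",
    "compute_ndwi",
    "c3_index",
    "shadow_direction_rowcol",
    "read_raster",
    "write_raster",
    "save_scene",
    "load_scene",
]


@dataclass(frozen=True)
class SolarGeometry:
    """Sun position at acquisition: altitude (elevation) and compass azimuth.

    altitude_deg
        Solar elevation angle β in (0, 90) degrees; drives H = L·tan β.
    azimuth_deg
        Compass direction of the sun in [0, 360), clockwise from grid north.
        Shadows fall along ``azimuth_deg + 180°``.
    """

    altitude_deg: float
    azimuth_deg: float

    def __post_init__(self) -> None:
        if not (0.0 < self.altitude_deg < 90.0):
            raise ValueError(f"solar altitude must be in (0, 90) deg, got {self.altitude_deg}")
        if not (0.0 <= self.azimuth_deg < 360.0):
            raise ValueError(f"solar azimuth must be in [0, 360) deg, got {self.azimuth_deg}")

    @property
    def shadow_azimuth_deg(self) -> float:
        return (self.azimuth_deg + 180.0) % 360.0

    @property
    def tan_altitude(self) -> float:
        return math.tan(math.radians(self.altitude_deg))


def shadow_direction_rowcol(solar: SolarGeometry) -> tuple[float, float]:
    """Unit vector (drow, dcol) of the shadow direction in grid coordinates.

    Compass angle θ maps to grid steps via north = −row, east = +col:
    (drow, dcol) = (−cos θ, sin θ).
    """
    theta = math.radians(solar.shadow_azimuth_deg)
    return (-math.cos(theta), math.sin(theta))


@dataclass
class MultispectralScene:
    """Co-registered 4-band multispectral stack plus optional panchromatic band.

    Bands are float arrays of digital numbers on a 0-255 scale, one shared
    shape; ``pixel_size`` is in metres per pixel.  ``origin`` is the world
    coordinate (x, y) of the grid's top-left corner, with y decreasing
    southward (row-down).
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    pixel_size: float
    solar: SolarGeometry
    pan: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        bands = {"blue": self.blue, "green": self.green, "red": self.red, "nir": self.nir}
        shapes = {name: np.asarray(b).shape for name, b in bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"multispectral bands must share one shape, got {shapes}")
        for name in bands:
            arr = np.asarray(bands[name], dtype=np.float64)
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise ValueError(f"band {name!r} must be finite and non-negative")
            setattr(self, name, arr)
        if self.pan is not None:
            self.pan = np.asarray(self.pan, dtype=np.float64)
            if self.pan.shape != self.blue.shape:
                raise ValueError("pan band must be resampled to the multispectral grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    def pixel_to_world(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of pixel centres."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(cols) + 0.5) * self.pixel_size
        y = y0 - (np.asarray(rows) + 0.5) * self.pixel_size
        return x, y

    @property
    def pan_or_brightness(self) -> np.ndarray:
        """The panchromatic band if present, else the multispectral brightness."""
        if self.pan is not None:
            return self.pan
        return compute_brightness(self).values


class IndexKind(str, Enum):
    PANTEX = "PANTEX"
    MBI = "MBI"
    MSI = "MSI"
    C3 = "C3"
    NDVI = "NDVI"
    NDWI = "NDWI"
    BRIGHTNESS = "BRIGHTNESS"


@dataclass
class IndexRaster:
    """Single-band derived index raster with a record of how it was computed."""

    values: np.ndarray
    kind: IndexKind
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.kind = IndexKind(self.kind)


def compute_brightness(scene: MultispectralScene) -> IndexRaster:
    """Per-pixel maximum over the four multispectral bands."""
    b = np.maximum.reduce([scene.blue, scene.green, scene.red, scene.nir])
    return IndexRaster(b, IndexKind.BRIGHTNESS)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den != 0)
    return out


def compute_ndvi(scene: MultispectralScene) -> IndexRaster:
    """Normalised-difference vegetation index (NIR − R)/(NIR + R); 0 where both are 0."""
    v = _safe_ratio(scene.nir - scene.red, scene.nir + scene.red)
    return IndexRaster(v, IndexKind.NDVI)


def compute_ndwi(scene: MultispectralScene) -> IndexRaster:
    """Normalised-difference water index (G − NIR)/(G + NIR); 0 where both are 0."""
    v = _safe_ratio(scene.green - scene.nir, scene.green + scene.nir)
    return IndexRaster(v, IndexKind.NDWI)


def c3_index(scene: MultispectralScene) -> IndexRaster:
    """Colour-invariant shadow channel c3 = arctan(B / max(R, G)).

    Convention at the degenerate denominator: max(R, G) = 0 with B > 0 gives
    π/2 (the arctan limit); an all-zero pixel gives 0.
    """
    den = np.maximum(scene.red, scene.green)
    v = np.arctan(_safe_ratio(scene.blue, den))
    v = np.where((den == 0) & (scene.blue > 0), np.pi / 2.0, v)
    return IndexRaster(v, IndexKind.C3)


# ---------------------------------------------------------------------------
# raster + scene I/O (plain TIFF with a JSON metadata sidecar)

def write_raster(path: str | Path, values: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


def read_raster(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(str(path)), dtype=np.float64)


def save_scene(scene: MultispectralScene, path: str | Path) -> None:
    """Write a scene as a multi-band TIFF plus ``<path>.json`` metadata."""
    import tifffile

    path = Path(path)
    bands = [scene.blue, scene.green, scene.red, scene.nir]
    names = ["blue", "green", "red", "nir"]
    if scene.pan is not None:
        bands.append(scene.pan)
        names.append("pan")
    tifffile.imwrite(str(path), np.stack(bands).astype(np.float32), photometric="minisblack")
    meta = {
        "bands": names,
        "pixel_size": scene.pixel_size,
        "origin": list(scene.origin),
        "sun_altitude_deg": scene.solar.altitude_deg,
        "sun_azimuth_deg": scene.solar.azimuth_deg,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_scene(path: str | Path) -> MultispectralScene:
    import tifffile

    path = Path(path)
    stack = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    named = dict(zip(meta["bands"], stack))
    return MultispectralScene(
        blue=named["blue"],
        green=named["green"],
        red=named["red"],
        nir=named["nir"],
        pan=named.get("pan"),
        pixel_size=float(meta["pixel_size"]),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        solar=SolarGeometry(float(meta["sun_altitude_deg"]), float(meta["sun_azimuth_deg"])),
    )
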