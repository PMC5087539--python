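"""Morphological building and shadow indices (MBI / MSI).

Both indices rest on top-hat-by-reconstruction granulometry: bright
(buildings) or dark (shadows) structures that are smaller than a linear
structuring element in some direction survive in the white (black) top-hat,
and the differential of the top-hat profile across structuring-element
lengths localises structures by size.  Averaging the absolute differential
profile over directions and scales gives the index.

Definitions used here, for brightness image b and linear SE of direction d,
length s:

* white top-hat  W_TH(d,s) = b − opening_by_reconstruction(b; d,s)
* black top-hat  B_TH(d,s) = closing_by_reconstruction(b; d,s) − b
* DMP(d,s_k)     = |TH(d, s_{k+1}) − TH(d, s_k)|
* MBI (MSI)      = Σ_{d,k} DMP(d,s_k) / (D × S)

with D directions and S scales (the printed normalisation uses S although
forward differencing yields S−1 terms per direction; kept as printed).
Black and white top-hats are duals: B_TH(b) = W_TH(M − b) for any constant
M ≥ max(b), hence MSI(b) = MBI applied to the inverted brightness image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import reconstruction

from .scene import IndexKind, IndexRaster, MultispectralScene, compute_brightness

__all__ = [
    "MorphConfig",
    "linear_se",
    "opening_by_reconstruction",
    "closing_by_reconstruction",
    "white_top_hat",
    "black_top_hat",
    "directional_mean",
    "dmp",
    "top_hat_profile",
    "mbi",
    "msi",
]


@dataclass(frozen=True)
class MorphConfig:
    """Granulometry parameters: SE directions and the length ladder.

    Defaults follow the study configuration: four directions and
    s = 2, 9, 16, ..., 65 (s_min=2, s_max=65, Δs=7, hence S = 10 scales).
    """

    directions: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    s_min: int = 2
    s_max: int = 65
    delta_s: int = 7

    def __post_init__(self) -> None:
        if self.s_min < 2:
            raise ValueError("s_min must be >= 2")
        if self.s_max < self.s_min:
            raise ValueError("s_max must be >= s_min")
        if self.delta_s < 1:
            raise ValueError("delta_s must be >= 1")
        if (self.s_max - self.s_min) % self.delta_s != 0:
            raise ValueError("(s_max - s_min) must be a multiple of delta_s")
        if len(self.directions) < 1:
            raise ValueError("at least one direction required")

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(range(self.s_min, self.s_max + 1, self.delta_s))

    @property
    def n_scales(self) -> int:
        return len(self.scales)


def linear_se(length: int, direction: float) -> np.ndarray:
    """Flat linear structuring element: a digital line of ``length`` pixels.

    ``direction`` is in degrees, 0 = horizontal (along columns), measured
    counter-clockwise in the (row, col) grid; 45 and 135 give diagonals.
    Arbitrary angles are rasterised with integer line drawing.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length == 1:
        return np.ones((1, 1), dtype=bool)
    theta = np.radians(direction)
    half = (length - 1) / 2.0
    # row axis points down, so a CCW angle maps to -sin on rows; normalising by
    # the Chebyshev norm makes `length` the pixel count along the digital line
    ur, uc = -np.sin(theta), np.cos(theta)
    cheb = max(abs(ur), abs(uc))
    dr, dc = ur / cheb * half, uc / cheb * half
    r0, c0 = int(round(-dr)), int(round(-dc))
    r1, c1 = int(round(dr)), int(round(dc))
    rr, cc = draw_line(r0, c0, r1, c1)
    rr -= rr.min()
    cc -= cc.min()
    se = np.zeros((rr.max() + 1, cc.max() + 1), dtype=bool)
    se[rr, cc] = True
    return se


def opening_by_reconstruction(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Erosion by ``se`` followed by geodesic reconstruction by dilation under ``img``."""
    img = np.asarray(img, dtype=np.float64)
    marker = ndimage.grey_erosion(img, footprint=se, mode="nearest")
    return reconstruction(marker, img, method="dilation")


def closing_by_reconstruction(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Dilation by ``se`` followed by geodesic reconstruction by erosion above ``img``.

    Dilation is taken as the adjoint of the erosion (reflected structuring
    element), which makes closing the exact dual of opening under image
    inversion even for even-length linear elements.
    """
    img = np.asarray(img, dtype=np.float64)
    marker = -ndimage.grey_erosion(-img, footprint=se, mode="nearest")
    return reconstruction(marker, img, method="erosion")


def white_top_hat(b: np.ndarray, direction: float, s: int) -> np.ndarray:
    """b minus its opening-by-reconstruction: bright structures thinner than the SE."""
    return np.asarray(b, dtype=np.float64) - opening_by_reconstruction(b, linear_se(s, direction))


def black_top_hat(b: np.ndarray, direction: float, s: int) -> np.ndarray:
    """Closing-by-reconstruction minus b: dark structures thinner than the SE."""
    return closing_by_reconstruction(b, linear_se(s, direction)) - np.asarray(b, dtype=np.float64)


def top_hat_profile(b: np.ndarray, cfg: MorphConfig, kind: str = "white") -> dict[tuple[float, int], np.ndarray]:
    """All per-(direction, scale) top-hat rasters."""
    op = white_top_hat if kind == "white" else black_top_hat
    return {(d, s): op(b, d, s) for d in cfg.directions for s in cfg.scales}


def directional_mean(profile: dict[tuple[float, int], np.ndarray], cfg: MorphConfig, s: int) -> np.ndarray:
    """Pointwise mean of the top-hat over directions at one scale."""
    return np.mean([profile[(d, s)] for d in cfg.directions], axis=0)


def dmp(profile: dict[tuple[float, int], np.ndarray], cfg: MorphConfig) -> dict[tuple[float, int], np.ndarray]:
    """Differential morphological profile: |forward difference| across scales,
    per direction (S−1 rasters per direction)."""
    scales = cfg.scales
    return {
        (d, scales[k]): np.abs(profile[(d, scales[k + 1])] - profile[(d, scales[k])])
        for d in cfg.directions
        for k in range(len(scales) - 1)
    }


def _morph_index(b: np.ndarray, cfg: MorphConfig, kind: str) -> np.ndarray:
    if cfg.n_scales < 2:
        raise ValueError("granulometry needs at least two scales (S >= 2)")
    profile = top_hat_profile(b, cfg, kind)
    diffs = dmp(profile, cfg)
    total = np.zeros_like(np.asarray(b, dtype=np.float64))
    for arr in diffs.values():
        total += arr
    return total / (len(cfg.directions) * cfg.n_scales)


def mbi(scene: MultispectralScene | np.ndarray, cfg: MorphConfig | None = None) -> IndexRaster:
    """Morphological building index of a scene (or of a raw brightness array)."""
    cfg = cfg or MorphConfig()
    b = scene if isinstance(scene, np.ndarray) else compute_brightness(scene).values
    return IndexRaster(_morph_index(b, cfg, "white"), IndexKind.MBI,
                       provenance={"scales": list(cfg.scales), "directions": list(cfg.directions)})


def msi(scene: MultispectralScene | np.ndarray, cfg: MorphConfig | None = None) -> IndexRaster:
    """Morphological shadow index: the black-top-hat counterpart of the MBI."""
    cfg = cfg or MorphConfig()
    b = scene if isinstance(scene, np.ndarray) else compute_brightness(scene).values
    return IndexRaster(_morph_index(b, cfg, "black"), IndexKind.MSI,
                       provenance={"scales": list(cfg.scales), "directions": list(cfg.directions)})
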