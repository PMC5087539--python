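"""PanTex built-up presence index.

Built-up areas show high gray-level co-occurrence contrast in *every*
direction, while linear features (roads, field edges) are high-contrast in
some directions only.  PanTex therefore evaluates GLCM contrast in a small
moving window for a set of displacement vectors covering distinct directions
and fuses them with a ``min`` operator: a pixel scores high only when all
directional contrasts are high.

Two computation routes exist:

* :func:`glcm` / :func:`glcm_contrast` build the explicit symmetric,
  normalised co-occurrence matrix of a window — transparent but slow.
* :func:`pantex_raster` uses the identity that the contrast of a normalised
  symmetric GLCM equals the mean of squared gray-level differences over the
  co-occurring pixel pairs, and evaluates that with integral-image box sums.
  Border windows are truncated (no padding), so no co-occurrences are ever
  fabricated outside the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import IndexKind, IndexRaster

__all__ = ["GlcmConfig", "Glcm", "glcm", "glcm_contrast", "quantize", "pantex_raster"]

#: ten displacement vectors with pairwise-distinct directions at Chebyshev
#: distance <= 2; the set is closed under 90-degree rotation up to sign.
DEFAULT_DISPLACEMENTS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 0), (1, 1), (1, -1),
    (0, 2), (2, 0), (2, 1), (1, 2), (2, -1), (1, -2),
)


@dataclass(frozen=True)
class GlcmConfig:
    levels: int = 256
    window_size: int = 7
    displacements: tuple[tuple[int, int], ...] = field(default=DEFAULT_DISPLACEMENTS)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        seen: set[tuple[int, int]] = set()
        for d in self.displacements:
            dr, dc = d
            if (dr, dc) == (0, 0):
                raise ValueError("displacement (0, 0) is not allowed")
            if (dr, dc) in seen or (-dr, -dc) in seen:
                raise ValueError(f"displacements must be distinct up to sign: {d}")
            seen.add((dr, dc))


@dataclass
class Glcm:
    """Normalised symmetric gray-level co-occurrence matrix P(i, j)."""

    p: np.ndarray  # (levels, levels), sums to 1 when any pair exists

    @property
    def levels(self) -> int:
        return self.p.shape[0]


def glcm(window: np.ndarray, displacement: tuple[int, int], levels: int) -> Glcm:
    """Symmetric normalised co-occurrence matrix of one (quantized) window.

    Each ordered pixel pair ``(p, p + displacement)`` with both ends inside
    the window is counted once; the count matrix is then symmetrised and
    normalised to frequencies.
    """
    w = np.asarray(window)
    if w.min() < 0 or w.max() >= levels:
        raise ValueError("window must be quantized to [0, levels)")
    dr, dc = displacement
    h, ww = w.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), ww - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"displacement {displacement} yields no pixel pairs in window")
    a = w[r0:r1, c0:c1].ravel()
    b = w[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    sym = counts + counts.T
    total = sym.sum()
    return Glcm(sym / total if total > 0 else sym)


def glcm_contrast(g: Glcm) -> float:
    """Contrast = sum over (i, j) of (i - j)^2 P(i, j)."""
    idx = np.arange(g.levels)
    d2 = (idx[:, None] - idx[None, :]) ** 2
    return float((d2 * g.p).sum())


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max rescale to integer gray levels [0, levels-1]."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.int64)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _integral(a: np.ndarray) -> np.ndarray:
    out = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=out[1:, 1:])
    return out


def _window_rect_sums(a: np.ndarray, r_off: tuple[int, int], c_off: tuple[int, int]) -> np.ndarray:
    """For each pixel (i, j), the sum of ``a`` over rows i+r_off[0]..i+r_off[1]
    and cols j+c_off[0]..j+c_off[1], intersected with the array domain."""
    h, w = a.shape
    integ = _integral(a)
    r0 = np.clip(np.arange(h) + r_off[0], 0, h)
    r1 = np.clip(np.arange(h) + r_off[1] + 1, 0, h)
    c0 = np.clip(np.arange(w) + c_off[0], 0, w)
    c1 = np.clip(np.arange(w) + c_off[1] + 1, 0, w)
    return (integ[np.ix_(r1, c1)] - integ[np.ix_(r0, c1)]
            - integ[np.ix_(r1, c0)] + integ[np.ix_(r0, c0)])


def pantex_raster(pan: np.ndarray, cfg: GlcmConfig | None = None) -> IndexRaster:
    """PanTex: per-pixel minimum over displacements of windowed GLCM contrast.

    The pan band is quantized to ``cfg.levels`` gray levels; for every
    displacement the window contrast equals the mean squared level
    difference over pairs fully inside the (truncated) centred window.
    """
    cfg = cfg or GlcmConfig()
    pan = np.asarray(pan, dtype=np.float64)
    h, w = pan.shape
    if cfg.window_size > min(h, w):
        raise ValueError("window larger than image")
    q = quantize(pan, cfg.levels).astype(np.float64)
    k = cfg.window_size // 2
    out = None
    for dr, dc in cfg.displacements:
        d2 = np.zeros((h, w))
        cnt = np.zeros((h, w))
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            contrast = np.zeros((h, w))
        else:
            diff = q[r0:r1, c0:c1] - q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            d2[r0:r1, c0:c1] = diff ** 2
            cnt[r0:r1, c0:c1] = 1.0
            # first pixel of a pair with both ends in the centred window
            r_off = (-k + max(0, -dr), k - max(0, dr))
            c_off = (-k + max(0, -dc), k - max(0, dc))
            num = _window_rect_sums(d2, r_off, c_off)
            den = _window_rect_sums(cnt, r_off, c_off)
            contrast = np.zeros((h, w))
            np.divide(num, den, out=contrast, where=den > 0)
        out = contrast if out is None else np.minimum(out, contrast)
    return IndexRaster(out, IndexKind.PANTEX, provenance={
        "levels": cfg.levels, "window_size": cfg.window_size,
        "displacements": list(cfg.displacements),
    })
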