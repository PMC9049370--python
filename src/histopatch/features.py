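"""Texture and color descriptors for histopathology patches.

Two complementary blocks are computed and cascaded:

* **CLBP** (completed local binary pattern) on the grayscale of the
  nuclei-segmented image. For every interior pixel with P neighbors on a
  circle of radius R (bilinear interpolation), the sign code
  S = Σ s(g_p − g_c)·2^p and the magnitude code
  M = Σ s(D_p − D_c)·2^p are formed, with D_p = |g_p − g_c| and D_c the
  mean magnitude (per-pixel by default, image-wide optionally), plus the
  center bit C = s(g_c − g_N) against the mean gray g_N; s(x) = 1 for
  x ≥ 0 and 0 otherwise. The descriptor is the uniform-pattern (u2)
  histogram of S concatenated with that of M — 59 + 59 = 118 bins at
  P = 8.

* **Color auto-correlogram** on the stain-separated foreground RGB:
  colors are quantized to 64 levels (4 per channel) and, for each color
  and each chessboard distance k ∈ {1, 3}, the probability that a pixel
  at distance exactly k from a pixel of that color shares the color —
  64 × 2 = 128 entries.

Cascading both blocks gives the 246-dimensional fused descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, DimensionError
from .segmentation import rgb_to_gray

__all__ = [
    "CLBPCodeMaps",
    "clbp_codes",
    "uniform_mapping",
    "clbp_descriptor",
    "color_quantize",
    "auto_correlogram",
    "fuse",
    "CLBPExtractor",
    "ColorCorrelogramExtractor",
    "TEXTURE_DIM",
    "COLOR_DIM",
    "FUSED_DIM",
]

TEXTURE_DIM = 118
COLOR_DIM = 128
FUSED_DIM = TEXTURE_DIM + COLOR_DIM


@dataclass
class CLBPCodeMaps:
    """Per-pixel CLBP codes over the valid interior region."""

    s_codes: np.ndarray
    m_codes: np.ndarray
    c_bits: np.ndarray
    P: int
    R: float


def _circle_offsets(P: int, R: float) -> np.ndarray:
    """Neighbor offsets (dy, dx) on the sampling circle.

    Neighbor p sits at angle 2πp/P, starting at (0, +R) and proceeding
    counter-clockwise in image coordinates (y down). Offsets within 1e-6
    of an integer are snapped so axis-aligned neighbors are sampled
    exactly.
    """
    p = np.arange(P)
    dx = R * np.cos(2 * np.pi * p / P)
    dy = -R * np.sin(2 * np.pi * p / P)
    off = np.stack([dy, dx], axis=1)
    snapped = np.rint(off)
    off[np.abs(off - snapped) < 1e-6] = snapped[np.abs(off - snapped) < 1e-6]
    return off


def _sample_neighbors(gray: np.ndarray, P: int, R: float) -> np.ndarray:
    """Bilinear neighbor stack of shape (P, Hv, Wv) over the valid region."""
    h, w = gray.shape
    b = int(np.ceil(R))
    hv, wv = h - 2 * b, w - 2 * b
    if hv <= 0 or wv <= 0:
        raise DimensionError(
            f"image {h}x{w} has no interior at radius {R}"
        )
    out = np.empty((P, hv, wv))
    for i, (dy, dx) in enumerate(_circle_offsets(P, R)):
        y0, x0 = int(np.floor(dy)), int(np.floor(dx))
        ty, tx = dy - y0, dx - x0
        # corner shifts with nonzero weight stay in bounds because
        # b = ceil(R); zero-weight corners are skipped (they may index
        # one past the interior when the offset is an exact integer)
        def block(sy, sx):
            return gray[b + sy : b + sy + hv, b + sx : b + sx + wv]

        acc = np.zeros((hv, wv))
        for sy, wy in ((y0, 1 - ty), (y0 + 1, ty)):
            for sx, wx in ((x0, 1 - tx), (x0 + 1, tx)):
                if wy * wx > 0:
                    acc += wy * wx * block(sy, sx)
        out[i] = acc
    return out


def clbp_codes(
    gray: np.ndarray,
    P: int = 8,
    R: float = 1.0,
    magnitude_threshold_mode: str = "local",
) -> CLBPCodeMaps:
    """Compute the S, M and C code maps of the completed LBP.

    ``magnitude_threshold_mode`` selects the magnitude threshold D_c:
    ``"local"`` uses the per-pixel mean of the P neighbor magnitudes,
    ``"global"`` the image-wide mean magnitude (the original CLBP
    convention).
    """
    if P < 4 or R < 1:
        raise ConfigError(f"require P >= 4 and R >= 1, got P={P}, R={R}")
    if magnitude_threshold_mode not in ("local", "global"):
        raise ConfigError(f"unknown threshold mode {magnitude_threshold_mode!r}")
    gray = np.asarray(gray, dtype=np.float64)
    b = int(np.ceil(R))
    centers = gray[b:-b, b:-b]
    neighbors = _sample_neighbors(gray, P, R)

    diffs = neighbors - centers[None]
    weights = (1 << np.arange(P)).astype(np.int64)
    s_codes = ((diffs >= 0).astype(np.int64) * weights[:, None, None]).sum(0)

    mags = np.abs(diffs)
    if magnitude_threshold_mode == "local":
        d_c = mags.mean(axis=0)[None]
    else:
        d_c = mags.mean()
    m_codes = ((mags - d_c >= 0).astype(np.int64) * weights[:, None, None]).sum(0)

    g_n = centers.mean()
    c_bits = (centers - g_n >= 0).astype(np.int64)
    return CLBPCodeMaps(s_codes, m_codes, c_bits, P, R)


@lru_cache(maxsize=None)
def uniform_mapping(P: int = 8) -> np.ndarray:
    """Map the 2^P codes to u2 histogram bins.

    Codes with at most two circular 0/1 transitions get their own bin (in
    ascending code order); every other code shares the final bin. For
    P = 8 this yields 58 + 1 = 59 bins.
    """
    if P > 16:
        raise ConfigError("uniform mapping supported only for P <= 16")
    codes = np.arange(1 << P)
    bits = (codes[:, None] >> np.arange(P)) & 1
    transitions = (bits != np.roll(bits, -1, axis=1)).sum(axis=1)
    uniform = transitions <= 2
    table = np.full(1 << P, uniform.sum(), dtype=np.int64)
    table[uniform] = np.arange(uniform.sum())
    return table


def n_uniform_bins(P: int = 8) -> int:
    return int(uniform_mapping(P).max()) + 1


def clbp_descriptor(codes: CLBPCodeMaps) -> np.ndarray:
    """u2 histogram of S codes ⊕ u2 histogram of M codes, L1-normalized.

    Length 2·59 = 118 at P = 8.
    """
    table = uniform_mapping(codes.P)
    nbins = int(table.max()) + 1
    blocks = []
    for cm in (codes.s_codes, codes.m_codes):
        hist = np.bincount(table[cm.ravel()], minlength=nbins).astype(np.float64)
        total = hist.sum()
        blocks.append(hist / total if total > 0 else hist)
    return np.concatenate(blocks)


def color_quantize(img: np.ndarray) -> np.ndarray:
    """Quantize RGB to 64 colors: index = 16·⌊R/64⌋ + 4·⌊G/64⌋ + ⌊B/64⌋."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise DimensionError(f"expected H×W×3 RGB, got {img.shape}")
    q = img.astype(np.int64) // 64
    return (16 * q[:, :, 0] + 4 * q[:, :, 1] + q[:, :, 2]).astype(np.int64)


def _offsets_at_linf(k: int) -> list[tuple[int, int]]:
    """All (dy, dx) with chessboard norm exactly k (8k offsets)."""
    offs = []
    for dy in range(-k, k + 1):
        for dx in range(-k, k + 1):
            if max(abs(dy), abs(dx)) == k:
                offs.append((dy, dx))
    return offs


def auto_correlogram(
    indexed: np.ndarray,
    distances: tuple[int, ...] = (1, 3),
    n_colors: int = 64,
) -> np.ndarray:
    """Color auto-correlogram over the given chessboard distances.

    Entry (i, k) estimates Pr[color(p₂) = i | color(p₁) = i, ‖p₁−p₂‖∞ = k]
    over ordered in-bounds pixel pairs; colors absent from the image (or
    with no valid pairs) contribute 0. Output is color-major then
    distance: index = i·len(distances) + k_index, length
    n_colors·len(distances).
    """
    if len(distances) == 0:
        raise ConfigError("distance set must be nonempty")
    indexed = np.asarray(indexed)
    if indexed.size == 0:
        raise DimensionError("empty index image")
    h, w = indexed.shape
    out = np.zeros((n_colors, len(distances)))
    for ki, k in enumerate(distances):
        match = np.zeros(n_colors)
        total = np.zeros(n_colors)
        for dy, dx in _offsets_at_linf(k):
            ys = slice(max(0, -dy), min(h, h - dy))
            xs = slice(max(0, -dx), min(w, w - dx))
            c1 = indexed[ys, xs]
            c2 = indexed[ys.start + dy : ys.stop + dy, xs.start + dx : xs.stop + dx]
            if c1.size == 0:
                continue
            total += np.bincount(c1.ravel(), minlength=n_colors)[:n_colors]
            same = c1[c1 == c2]
            match += np.bincount(same.ravel(), minlength=n_colors)[:n_colors]
        nz = total > 0
        out[nz, ki] = match[nz] / total[nz]
    return out.ravel()


def fuse(texture: np.ndarray, color: np.ndarray) -> np.ndarray:
    """Cascade the texture and color blocks (texture first)."""
    texture = np.asarray(texture, dtype=np.float64)
    color = np.asarray(color, dtype=np.float64)
    if texture.shape != (TEXTURE_DIM,):
        raise DimensionError(
            f"texture block must have length {TEXTURE_DIM}, got {texture.shape}"
        )
    if color.shape != (COLOR_DIM,):
        raise DimensionError(
            f"color block must have length {COLOR_DIM}, got {color.shape}"
        )
    return np.concatenate([texture, color])


class CLBPExtractor(TransformerMixin, BaseEstimator):
    """Transform images into 118-dim CLBP texture descriptors.

    Accepts grayscale (H×W) or RGB (H×W×3, converted by ITU-R 601
    luminance) images.
    """

    def __init__(
        self, P: int = 8, R: float = 1.0, magnitude_threshold_mode: str = "local"
    ):
        self.P = P
        self.R = R
        self.magnitude_threshold_mode = magnitude_threshold_mode

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for img in X:
            img = np.asarray(img)
            gray = rgb_to_gray(img) if img.ndim == 3 else img
            codes = clbp_codes(
                gray, self.P, self.R, self.magnitude_threshold_mode
            )
            rows.append(clbp_descriptor(codes))
        return np.asarray(rows)


class ColorCorrelogramExtractor(TransformerMixin, BaseEstimator):
    """Transform RGB images into 128-dim color auto-correlograms."""

    def __init__(self, distances: tuple[int, ...] = (1, 3), n_colors: int = 64):
        self.distances = distances
        self.n_colors = n_colors

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(
            [
                auto_correlogram(
                    color_quantize(img), tuple(self.distances), self.n_colors
                )
                for img in X
            ]
        )
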