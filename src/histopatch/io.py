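"""Image and mask I/O plus the patch-based preprocessing steps.

Whole-slide scans are first downscaled by 0.5× and then sampled as random
square patches; patches inherit the class label of their parent image so a
patch-wise classifier can be trained from image-level annotations.

Conventions: RGB channel order, 0-based row-major (y, x) pixel coordinates,
8-bit intensities in [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import downscale_local_mean

from .exceptions import DimensionError, FormatError

__all__ = [
    "PatchRecord",
    "load_image",
    "write_image",
    "rescale_half",
    "random_patches",
    "write_mask",
    "read_mask",
    "read_manifest",
    "write_manifest",
]


@dataclass
class PatchRecord:
    """A square patch cropped verbatim from a parent image."""

    patch: np.ndarray
    parent_id: str
    patch_index: int
    label: str | None = None
    top: int = 0
    left: int = 0


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an 8-bit H×W×3 RGB array.

    Grayscale images are replicated to 3 channels, an alpha channel is
    dropped, and 16-bit data is rescaled to 8-bit by integer division
    by 257. No color-profile transforms are applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by plugin
        raise FormatError(f"could not decode image {path}: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"image {path} decoded to an empty array")
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"unsupported image dtype {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise FormatError(f"image {path} has unsupported shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise FormatError(f"image {path} has {arr.shape[2]} channels")
    return np.ascontiguousarray(arr)


def write_image(img: np.ndarray, path) -> None:
    """Write an 8-bit RGB (or grayscale) array to disk."""
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def rescale_half(img: np.ndarray) -> np.ndarray:
    """Downscale an RGB image by exactly 0.5× per axis.

    Implemented as 2×2 block averaging (bilinear interpolation at the
    aligned 0.5 scale), with rounding half-to-even to 8-bit. Odd trailing
    rows/columns are dropped (output dimensions are floor(input/2)).
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    img = img[: h - h % 2, : w - w % 2]
    if img.ndim == 2:
        out = downscale_local_mean(img.astype(np.float64), (2, 2))
    else:
        out = downscale_local_mean(img.astype(np.float64), (2, 2, 1))
    return np.rint(out).clip(0, 255).astype(np.uint8)


def random_patches(
    img: np.ndarray,
    n: int = 20,
    size: int = 512,
    seed: int = 0,
    parent_id: str = "",
    label: str | None = None,
) -> list[PatchRecord]:
    """Crop ``n`` random ``size``×``size`` patches from an image.

    Top-left corners are drawn uniformly with replacement over the valid
    range (overlapping patches permitted), reproducibly for a given seed.
    Patches are verbatim sub-arrays: no resampling is involved.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h < size or w < size:
        raise DimensionError(
            f"image {h}x{w} is smaller than the patch size {size}"
        )
    rng = np.random.default_rng(seed)
    tops = rng.integers(0, h - size + 1, n)
    lefts = rng.integers(0, w - size + 1, n)
    return [
        PatchRecord(
            patch=img[t : t + size, l : l + size].copy(),
            parent_id=parent_id,
            patch_index=i,
            label=label,
            top=int(t),
            left=int(l),
        )
        for i, (t, l) in enumerate(zip(tops, lefts))
    ]


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary or integer label mask losslessly as PNG.

    Binary masks are stored as 8-bit; label masks as 16-bit (at most
    65535 labels).
    """
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer) and mask.dtype != bool:
        raise TypeError(f"mask must be integer-typed, got {mask.dtype}")
    mask = mask.astype(np.int64)
    if mask.min() < 0:
        raise ValueError("mask values must be non-negative")
    if mask.max() > 65535:
        raise OverflowError("more than 65535 labels cannot be stored as PNG")
    dtype = np.uint8 if mask.max() <= 255 else np.uint16
    iio.imwrite(Path(path), mask.astype(dtype))


def read_mask(path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` (lossless round trip)."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"mask file {path} is not single-channel")
    return arr.astype(np.int64 if arr.max() > 1 else np.uint8)


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV (image_path, label, split)."""
    df = pd.read_csv(path)
    required = {"image_path", "label", "split"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
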