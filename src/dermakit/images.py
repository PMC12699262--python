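"""Raster conventions shared across the package.

Images are plain numpy arrays:

* ``RgbImage`` — ``uint8`` array of shape ``(H, W, 3)``.
* ``MaskImage`` — ``bool`` array of shape ``(H, W)``.

Coordinates are ``(row, col)``, 0-based; crops are half-open
``[r, r+size) x [c, c+size)``.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = [
    "as_rgb",
    "as_mask",
    "load_rgb",
    "load_mask",
    "save_rgb",
    "save_mask",
    "rgb_to_gray",
    "optical_density",
]

#: Hematoxylin direction in optical-density space (Ruifrok & Johnston), unit norm.
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
HEMATOXYLIN_OD = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)


def as_rgb(image: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to the RGB uint8 convention."""
    a = np.asarray(image)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {a.shape}")
    if a.dtype != np.uint8:
        a = np.clip(np.rint(a), 0, 255).astype(np.uint8)
    return a


def as_mask(mask: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to the binary mask convention."""
    a = np.asarray(mask)
    if a.ndim != 2:
        raise ValueError(f"expected 2-D mask array, got shape {a.shape}")
    return a > 0 if a.dtype != bool else a


def load_rgb(path) -> np.ndarray:
    a = iio.imread(path)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    return as_rgb(a[..., :3])


def load_mask(path) -> np.ndarray:
    a = iio.imread(path)
    if a.ndim == 3:
        a = a[..., 0]
    return as_mask(a)


def save_rgb(path, image: np.ndarray) -> None:
    iio.imwrite(path, as_rgb(image))


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (as_mask(mask).astype(np.uint8)) * 255)


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale (0.299 R + 0.587 G + 0.114 B), float64 in [0, 255]."""
    a = as_rgb(image).astype(np.float64)
    return 0.299 * a[..., 0] + 0.587 * a[..., 1] + 0.114 * a[..., 2]


def optical_density(image: np.ndarray, i0: float = 256.0) -> np.ndarray:
    """Per-channel optical density, ``-log10((I + 1) / I0)``.

    The +1 shift avoids log(0) on saturated black pixels; ``I0 = 256`` so a
    pure-white pixel (255) has OD exactly 0.
    """
    a = as_rgb(image).astype(np.float64)
    return -np.log10((a + 1.0) / i0)
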