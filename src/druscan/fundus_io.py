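"""Raster I/O and channel extraction for fundus images.

Images are plain :mod:`numpy` arrays throughout the package:

* RGB image  — ``(height, width, 3)`` ``uint8``
* gray image — ``(height, width)`` ``uint8``
* binary mask — ``(height, width)`` ``bool``

Pixel coordinates are ``(row, col)``, 0-based, origin at the top-left.

Drusen, vessels and the optic disc all have their highest contrast in the
green plane of a fundus photograph, so the pipeline operates on the green
channel exclusively; the red plane is dominated by choroidal reflectance and
illumination, the blue plane carries little signal.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

log = logging.getLogger(__name__)

__all__ = ["read_image", "green_channel", "write_mask", "read_mask"]


def _to_uint8(arr: np.ndarray, path: str) -> np.ndarray:
    """Coerce a decoded raster to 8-bit, rescaling 16-bit data."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        log.warning("%s: 16-bit raster rescaled to 8-bit (integer division by 257)", path)
        return (arr // 257).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        log.warning("%s: float raster clipped and cast to 8-bit", path)
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.max <= 255:
            return arr.astype(np.uint8)
        log.warning("%s: %s raster rescaled to 8-bit", path, arr.dtype)
        return (arr.astype(np.int64) * 255 // info.max).astype(np.uint8)
    raise OSError(f"cannot read {path!r}: unsupported pixel type {arr.dtype}")


def read_image(path) -> np.ndarray:
    """Read a raster file as an ``(H, W, 3)`` uint8 RGB array.

    Grayscale files are promoted to three equal planes; an alpha channel
    (32-bit RGBA) is dropped. 16-bit inputs are rescaled to 8-bit with a
    logged warning.

    Raises
    ------
    OSError
        If the file does not exist or cannot be decoded.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures vary by backend
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise OSError(f"cannot read image {path}: unexpected shape {arr.shape}")
    return _to_uint8(arr, str(path))


def green_channel(img: np.ndarray) -> np.ndarray:
    """Return the green plane of an RGB image, unchanged, as uint8."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    return np.ascontiguousarray(img[:, :, 1], dtype=np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground 255, background 0)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected 2-D mask, got shape {mask.shape}")
    out = np.where(mask.astype(bool), np.uint8(255), np.uint8(0))
    try:
        iio.imwrite(Path(path), out)
    except Exception as exc:
        raise OSError(f"cannot write mask {path}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a mask raster; any nonzero pixel is foreground."""
    arr = iio.imread(Path(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return arr > 0
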