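"""Dual-scale median filtering: the drusen candidate (subtract) image.

Drusen are small bright spots, typically a few to ~15 pixels across. A
median filter removes any structure smaller than (roughly half) its window,
so filtering with a window larger than every druse yields a background
estimate in which drusen have vanished while the illumination gradient and
large anatomy survive. Subtracting that background from a lightly
denoised copy of the image (small window, which removes impulse noise but
not drusen) leaves a difference image in which drusen are bright on a
near-zero background. A final min-max histogram stretch spreads the
difference image over the full 8-bit range before thresholding.

Window-size defaults are 5 (denoising) and 30 (background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import rank as _rank

from .errors import InvalidParameterError

__all__ = ["MedianFilterSpec", "median_filter", "subtract_candidates", "histogram_stretch"]


@dataclass(frozen=True)
class MedianFilterSpec:
    """Window sides for the dual-scale median difference.

    ``small_mask`` must be odd (a centered denoising window);
    ``large_mask`` must exceed the largest drusen diameter of interest.
    """

    small_mask: int = 5
    large_mask: int = 30

    def __post_init__(self):
        if self.small_mask % 2 == 0:
            raise InvalidParameterError(f"small_mask must be odd, got {self.small_mask}")
        if not 1 <= self.small_mask < self.large_mask:
            raise InvalidParameterError(
                f"need 1 <= small_mask < large_mask, got {self.small_mask}, {self.large_mask}"
            )


def median_filter(gray: np.ndarray, mask_side: int) -> np.ndarray:
    """Square-window median filter with replicate border padding.

    Odd windows are centered on the output pixel. Even windows are anchored
    so the output pixel sits at offset ``(side/2 - 1, side/2 - 1)`` within
    the window (e.g. offset (14, 14) in a 30x30 window), and the lower
    median (the ``(n//2)``-th smallest of the n window values) is taken —
    a deterministic convention for the even-count median.

    Implemented with a sliding-histogram rank filter, which is exact for
    8-bit data. The even-window case is reduced to the odd-style centered
    rank filter by negating intensities and flipping both axes: the lower
    median of values in a window spanning offsets ``-(s/2-1)..+s/2`` equals
    255 minus the upper median of the negated, flipped image over the
    mirrored window.

    Raises
    ------
    InvalidParameterError
        If ``mask_side < 1`` or the window exceeds both image dimensions.
    """
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        raise InvalidParameterError(f"median_filter expects uint8, got {gray.dtype}")
    s = int(mask_side)
    if s < 1:
        raise InvalidParameterError(f"mask_side must be >= 1, got {mask_side}")
    h, w = gray.shape
    if s > h and s > w:
        raise InvalidParameterError(
            f"mask_side {s} exceeds both image dimensions {h}x{w}"
        )
    if s == 1:
        return gray.copy()
    pad = s // 2
    footprint = np.ones((s, s), dtype=bool)
    if s % 2 == 1:
        padded = np.pad(gray, pad, mode="edge")
        out = _rank.median(padded, footprint=footprint)
        return out[pad:-pad, pad:-pad]
    # Even window: negate + flip reduces lower-median/anchor-(s/2-1) to the
    # rank filter's native upper-median/anchor-(s/2) convention.
    padded = np.pad(gray, pad, mode="edge")
    flipped = (255 - padded)[::-1, ::-1]
    out = _rank.median(flipped, footprint=footprint)
    out = (255 - out)[::-1, ::-1]
    return out[pad:-pad, pad:-pad]


def subtract_candidates(gray: np.ndarray, spec: MedianFilterSpec | None = None) -> np.ndarray:
    """Difference of the two median-filtered images, clamped to [0, 255].

    ``median(gray, small) - median(gray, large)``: bright structures smaller
    than the large window survive with positive values; the background and
    smooth illumination cancel; dark structures clamp to zero (only bright
    drusen are sought).
    """
    spec = spec or MedianFilterSpec()
    small = median_filter(gray, spec.small_mask).astype(np.int16)
    large = median_filter(gray, spec.large_mask).astype(np.int16)
    return np.clip(small - large, 0, 255).astype(np.uint8)


def histogram_stretch(gray: np.ndarray) -> np.ndarray:
    """Linear min-max stretch to the full 8-bit range.

    ``v -> floor(255 * (v - min) / (max - min))``. A constant image (zero
    dynamic range) maps to all zeros so that drusen-free inputs flow through
    the pipeline instead of erroring.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise InvalidParameterError("cannot stretch an empty image")
    lo = int(gray.min())
    hi = int(gray.max())
    if hi == lo:
        return np.zeros_like(gray, dtype=np.uint8)
    out = (gray.astype(np.int32) - lo) * 255 // (hi - lo)
    return out.astype(np.uint8)
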