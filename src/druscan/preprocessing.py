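"""Optic-disc detection and macular region-of-interest construction.

The optic disc is the brightest structure in a fundus image. It is found by
binarizing the green channel at a high intensity cutoff (default: strictly
greater than 200), labeling connected components, and keeping the largest
one. The macular ROI is then built geometrically: drusen cluster around the
fovea, which sits roughly midway between the disc and the opposite image
edge. The ROI is the circle centered on that midpoint whose radius is the
midpoint-to-disc distance, so the disc centroid lies on the ROI boundary and
the fovea estimate at its center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidGeometryError, NoOpticDiscError

__all__ = ["OpticDisc", "RoiCircle", "detect_optic_disc", "compute_roi", "roi_mask"]


@dataclass(frozen=True)
class OpticDisc:
    """Largest bright connected component of the green channel.

    ``centroid`` is the component centroid (mean member coordinate, rounded
    half-up to integers); ``side`` records which image half the disc
    occupies, which orients the ROI construction.
    """

    centroid: tuple[int, int]  # (row, col)
    pixel_count: int
    mask: np.ndarray  # bool (H, W)
    side: str  # "left" | "right"

    @property
    def radius(self) -> float:
        """Equivalent-circle radius sqrt(area / pi), in pixels."""
        return float(np.sqrt(self.pixel_count / np.pi))


@dataclass(frozen=True)
class RoiCircle:
    center: tuple[int, int]  # (row, col)
    radius: float


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def detect_optic_disc(
    gray: np.ndarray,
    intensity_threshold: int = 200,
    connectivity: int = 8,
) -> OpticDisc:
    """Locate the optic disc by threshold-and-label.

    Pixels strictly brighter than ``intensity_threshold`` are labeled
    (8-connectivity by default, so diagonally touching bright blobs merge)
    and the largest component is taken as the disc. Ties between equal-sized
    components resolve to the lowest label (first in raster order).

    Raises
    ------
    NoOpticDiscError
        If no pixel exceeds the threshold.
    """
    gray = np.asarray(gray)
    bright = gray > intensity_threshold
    if not bright.any():
        raise NoOpticDiscError(
            f"no pixel brighter than {intensity_threshold}; cannot locate optic disc"
        )
    structure = ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndi.label(bright, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background
    disc_label = int(np.argmax(sizes))
    mask = labels == disc_label
    rows, cols = np.nonzero(mask)
    centroid = (_round_half_up(rows.mean()), _round_half_up(cols.mean()))
    side = "left" if centroid[1] < gray.shape[1] / 2 else "right"
    return OpticDisc(centroid=centroid, pixel_count=int(sizes[disc_label]), mask=mask, side=side)


def compute_roi(disc: OpticDisc, width: int, height: int) -> RoiCircle:
    """Build the macular ROI circle from the detected disc.

    The ROI center is the midpoint of the horizontal segment from the disc
    centroid to the far image edge (column ``width - 1`` for a left-side
    disc, column 0 for a right-side disc), taken at the disc centroid's row.
    Half-pixel midpoints round toward the disc, which makes the construction
    exactly equivariant under horizontal mirroring. The radius is the
    distance from the ROI center back to the disc centroid, i.e. the
    estimated fovea-to-disc distance.

    Raises
    ------
    InvalidGeometryError
        If the disc centroid lies on the opposite edge (zero radius).
    """
    row, col = disc.centroid
    if disc.side == "left":
        edge = width - 1
        mid = int(np.floor((col + edge) / 2))  # round half toward the disc
    else:
        edge = 0
        mid = int(np.ceil(col / 2))
    radius = abs(mid - col)
    if radius <= 0:
        raise InvalidGeometryError(
            f"disc centroid column {col} coincides with the opposite edge; ROI degenerates"
        )
    return RoiCircle(center=(row, mid), radius=float(radius))


def roi_mask(roi: RoiCircle, width: int, height: int) -> np.ndarray:
    """Rasterize an ROI circle: true where (r-cr)^2 + (c-cc)^2 <= radius^2."""
    rr, cc = np.ogrid[:height, :width]
    cr, ccol = roi.center
    return (rr - cr) ** 2 + (cc - ccol) ** 2 <= roi.radius**2
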