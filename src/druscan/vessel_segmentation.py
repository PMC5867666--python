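"""Vessel segmentation by seeded region growing.

Retinal vessels all emerge from the optic disc and are the darkest
structures in the green channel, so seeds are picked in an annulus just
outside the disc (where vessels must cross) at the locally darkest
intensities, and grown by intensity similarity: a pixel joins the region
when its intensity differs from the seed's by at most ``tolerance``. The
grown vessel tree, unioned with the disc and dilated, forms the "non-drusen"
exclusion mask that removes bright false candidates hugging vessels and the
disc rim in the difference image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidGeometryError, RegionOverflowError
from .preprocessing import OpticDisc

__all__ = [
    "RegionGrowParams",
    "select_vessel_seed",
    "region_grow",
    "grow_vessel_tree",
    "nondrusen_mask",
]


@dataclass(frozen=True)
class RegionGrowParams:
    """Region-growing controls.

    ``tolerance`` — admissible absolute intensity difference from the seed;
    ``connectivity`` — 4 or 8 neighbors;
    ``max_region_fraction`` — abort when the region exceeds this fraction of
    the image (a region that large is background, not vessel).
    """

    tolerance: int = 15
    connectivity: int = 8
    max_region_fraction: float = 0.25

    def __post_init__(self):
        if self.tolerance < 0:
            raise ValueError(f"tolerance must be >= 0, got {self.tolerance}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if not 0.0 < self.max_region_fraction <= 1.0:
            raise ValueError(
                f"max_region_fraction must be in (0, 1], got {self.max_region_fraction}"
            )


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def _seed_annulus(gray: np.ndarray, disc: OpticDisc) -> np.ndarray:
    """Annulus (r_disc, 2*r_disc] around the disc centroid, clipped to image."""
    h, w = gray.shape
    r_disc = disc.radius
    rr, cc = np.ogrid[:h, :w]
    d2 = (rr - disc.centroid[0]) ** 2 + (cc - disc.centroid[1]) ** 2
    return (d2 > r_disc**2) & (d2 <= (2.0 * r_disc) ** 2)


def select_vessel_seed(gray: np.ndarray, disc: OpticDisc) -> tuple[int, int]:
    """Darkest pixel in the annulus just outside the disc boundary.

    Vessels are the darkest green-channel structures leaving the disc, so
    the annulus minimum sits on a vessel. Ties resolve to the first pixel in
    row-major order.

    Raises
    ------
    InvalidGeometryError
        If the annulus does not intersect the image (disc fills the frame).
    """
    gray = np.asarray(gray)
    annulus = _seed_annulus(gray, disc)
    flat = np.flatnonzero(annulus)
    if flat.size == 0:
        raise InvalidGeometryError("seed annulus is empty; disc fills the image")
    vals = gray.ravel()[flat]
    idx = int(flat[int(np.argmin(vals))])  # argmin -> first occurrence, row-major
    return (idx // gray.shape[1], idx % gray.shape[1])


def region_grow(
    gray: np.ndarray, seed: tuple[int, int], params: RegionGrowParams | None = None
) -> np.ndarray:
    """Flood from ``seed``, admitting pixels within ``tolerance`` of the
    seed intensity, under the configured connectivity.

    The result is the connected component of the seed inside the admissible
    set |I - I(seed)| <= tolerance, computed by geodesic binary propagation.

    Raises
    ------
    RegionOverflowError
        If the grown region exceeds ``max_region_fraction`` of the image.
    """
    params = params or RegionGrowParams()
    gray = np.asarray(gray)
    h, w = gray.shape
    r, c = seed
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"seed {seed} outside image {h}x{w}")
    seed_val = int(gray[r, c])
    admissible = np.abs(gray.astype(np.int16) - seed_val) <= params.tolerance
    start = np.zeros_like(admissible)
    start[r, c] = True
    region = ndi.binary_propagation(
        start, mask=admissible, structure=_structure(params.connectivity)
    )
    fraction = region.sum() / region.size
    if fraction > params.max_region_fraction:
        raise RegionOverflowError(fraction, params.max_region_fraction)
    return region


def grow_vessel_tree(
    gray: np.ndarray,
    disc: OpticDisc,
    params: RegionGrowParams | None = None,
    n_sectors: int = 8,
    min_seed_contrast: int | None = None,
) -> np.ndarray:
    """Union of regions grown from one seed set per annulus sector.

    A single seed can miss vessel branches on the disc's far side, so the
    seed annulus is split into ``n_sectors`` angular sectors and every pixel
    attaining the sector's minimum intensity is used as a seed (taking all
    minima keeps the choice free of arbitrary tie-breaks). A sector's seeds
    are used only if they are at least ``min_seed_contrast`` darker than the
    image median — a brighter minimum means the sector holds no vessel.
    Seeds whose regions overflow ``max_region_fraction`` are discarded as
    background matches rather than failing the segmentation.
    """
    params = params or RegionGrowParams()
    if min_seed_contrast is None:
        min_seed_contrast = params.tolerance
    gray = np.asarray(gray)
    annulus = _seed_annulus(gray, disc)
    if not annulus.any():
        raise InvalidGeometryError("seed annulus is empty; disc fills the image")
    rows, cols = np.nonzero(annulus)
    angles = np.arctan2(rows - disc.centroid[0], cols - disc.centroid[1])
    sector = np.floor((angles + np.pi) / (2 * np.pi) * n_sectors).astype(int)
    sector = np.clip(sector, 0, n_sectors - 1)
    darkness_cutoff = float(np.median(gray)) - float(min_seed_contrast)

    vessels = np.zeros(gray.shape, dtype=bool)
    vals = gray[rows, cols]
    for s in range(n_sectors):
        in_sector = sector == s
        if not in_sector.any():
            continue
        vmin = vals[in_sector].min()
        if vmin > darkness_cutoff:
            continue  # no dark structure crosses this sector
        for r, c in zip(rows[in_sector][vals[in_sector] == vmin],
                        cols[in_sector][vals[in_sector] == vmin]):
            if vessels[r, c]:
                continue  # same component as an earlier seed
            try:
                vessels |= region_grow(gray, (int(r), int(c)), params)
            except RegionOverflowError:
                continue  # seed matched background; not a vessel
    return vessels


def nondrusen_mask(
    vessels: np.ndarray, disc: OpticDisc, dilation_radius: int = 2
) -> np.ndarray:
    """Dilated union of the vessel and disc masks.

    Bright rims flank vessels and the disc in the median-difference image;
    dilating the exclusion mask (square 8-connected element, iterated
    ``dilation_radius`` times, i.e. a Chebyshev ball) absorbs them.
    """
    vessels = np.asarray(vessels, dtype=bool)
    if vessels.shape != disc.mask.shape:
        raise ValueError("vessel and disc masks must share dimensions")
    union = vessels | disc.mask
    if dilation_radius > 0 and union.any():
        union = ndi.binary_dilation(
            union, structure=_structure(8), iterations=int(dilation_radius)
        )
    return union
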