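"""End-to-end drusen segmentation.

Stage order: green channel -> optic-disc detection -> ROI construction ->
dual-scale median difference -> histogram stretch -> ROI histogram ->
Renyi-entropy threshold -> binarization inside the ROI -> removal of the
dilated vessel/disc (non-drusen) mask -> minimum-area filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .candidate_detection import MedianFilterSpec, histogram_stretch, subtract_candidates
from .entropy_thresholding import (
    RenyiThresholdResult,
    apply_threshold,
    component_threshold,
    histogram,
    otsu_threshold,
    renyi_threshold,
)
from .errors import DruscanError, PipelineStageError
from .fundus_io import green_channel
from .preprocessing import OpticDisc, RoiCircle, compute_roi, detect_optic_disc, roi_mask
from .vessel_segmentation import RegionGrowParams, grow_vessel_tree, nondrusen_mask

__all__ = ["DiscConfig", "VesselConfig", "RenyiConfig", "PipelineConfig",
           "SegmentationResult", "segment_drusen"]


@dataclass(frozen=True)
class DiscConfig:
    intensity_threshold: int = 200
    connectivity: int = 8


@dataclass(frozen=True)
class VesselConfig:
    tolerance: int = 15
    connectivity: int = 8
    max_region_fraction: float = 0.25
    dilation_radius: int = 2
    n_seeds: int = 8  # annulus sectors seeded around the disc

    def grow_params(self) -> RegionGrowParams:
        return RegionGrowParams(
            tolerance=self.tolerance,
            connectivity=self.connectivity,
            max_region_fraction=self.max_region_fraction,
        )


@dataclass(frozen=True)
class RenyiConfig:
    alpha_low: float = 0.5
    alpha_high: float = 2.0


@dataclass(frozen=True)
class PipelineConfig:
    disc: DiscConfig = field(default_factory=DiscConfig)
    median: MedianFilterSpec = field(default_factory=MedianFilterSpec)
    vessel: VesselConfig = field(default_factory=VesselConfig)
    renyi: RenyiConfig = field(default_factory=RenyiConfig)
    min_drusen_area: int = 4  # set 0 to disable the post-filter


@dataclass
class SegmentationResult:
    """All products of one segmentation run.

    ``drusen_mask`` is guaranteed to lie inside the ROI circle and to be
    disjoint from the dilated vessel/disc exclusion mask. ``threshold`` is
    the full Renyi decomposition when the Renyi method ran, else ``None``;
    ``threshold_value`` is the gray-level cut actually applied.
    """

    drusen_mask: np.ndarray
    roi: RoiCircle
    disc: OpticDisc
    vessel_mask: np.ndarray
    threshold: Optional[RenyiThresholdResult]
    threshold_value: int
    intermediates: dict = field(default_factory=dict)

    @property
    def drusen_area(self) -> int:
        return int(self.drusen_mask.sum())


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, DruscanError) and not isinstance(
                exc, PipelineStageError
            ):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def _drop_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 1 or not mask.any():
        return mask
    structure = ndi.generate_binary_structure(2, 2)
    labels, n = ndi.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[labels]


def segment_drusen(
    img: np.ndarray,
    cfg: PipelineConfig | None = None,
    threshold_method: str = "renyi",
    keep_intermediates: bool = False,
) -> SegmentationResult:
    """Segment drusen in an 8-bit RGB fundus image.

    ``threshold_method`` selects the automatic threshold: ``"renyi"`` (the
    three-component blend), ``"max_entropy"`` (the Shannon component alone)
    or ``"otsu"`` (between-class variance baseline).

    Stage failures raise :class:`PipelineStageError` naming the stage.
    """
    cfg = cfg or PipelineConfig()
    img = np.asarray(img)
    green = green_channel(img)
    h, w = green.shape

    with _stage("optic_disc"):
        disc = detect_optic_disc(
            green, cfg.disc.intensity_threshold, cfg.disc.connectivity
        )
    with _stage("roi"):
        roi = compute_roi(disc, width=w, height=h)
    roim = roi_mask(roi, width=w, height=h)

    with _stage("candidate_detection"):
        subtract = subtract_candidates(green, cfg.median)
        stretched = histogram_stretch(subtract)

    with _stage("threshold"):
        hist = histogram(stretched, roim)
        renyi: Optional[RenyiThresholdResult] = None
        if threshold_method == "renyi":
            renyi = renyi_threshold(hist, cfg.renyi.alpha_low, cfg.renyi.alpha_high)
            t = renyi.t_c
        elif threshold_method == "max_entropy":
            t = component_threshold(hist, 1.0)
        elif threshold_method == "otsu":
            t = otsu_threshold(hist)
        else:
            raise ValueError(f"unknown threshold_method {threshold_method!r}")
        candidates = apply_threshold(stretched, t, roim)

    with _stage("vessel_removal"):
        vessels = grow_vessel_tree(
            green, disc, cfg.vessel.grow_params(), n_sectors=cfg.vessel.n_seeds
        )
        exclusion = nondrusen_mask(vessels, disc, cfg.vessel.dilation_radius)

    drusen = candidates & ~exclusion
    drusen = _drop_small_components(drusen, cfg.min_drusen_area)

    result = SegmentationResult(
        drusen_mask=drusen,
        roi=roi,
        disc=disc,
        vessel_mask=vessels,
        threshold=renyi,
        threshold_value=int(t),
    )
    if keep_intermediates:
        result.intermediates = {
            "green": green,
            "subtract": subtract,
            "stretched": stretched,
            "roi_mask": roim,
            "candidates": candidates,
            "exclusion": exclusion,
        }
    return result
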