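"""Two-level agreement scoring between automatic and manual drusen masks.

Pixel-by-pixel scoring compares every pixel inside the ROI and supports
sensitivity, specificity, accuracy and the Dice similarity coefficient
(DSC = 2TP / (2TP + FP + FN)). Region-by-region scoring compares connected
lesions: a true lesion touched by any predicted pixel is a TP, an untouched
one an FN, and a predicted component touching no true lesion an FP; true
negatives are undefined at region level, so specificity and accuracy are
omitted there.

For paired drusen-area measurements (manual vs automatic, one pair per
image) the module provides Pearson correlation, the two-way random-effects
absolute-agreement single-measures intraclass correlation ICC(2,1) with its
95% CI, and Bland-Altman limits of agreement (mean difference +/- 1.96 SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .errors import EmptyRegionError

__all__ = [
    "ConfusionCounts",
    "ConditionalProbabilities",
    "BlandAltman",
    "AgreementStats",
    "confusion_pixelwise",
    "confusion_regionwise",
    "conditional_probabilities",
    "agreement_stats",
    "agreement_plots",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: Optional[int]  # None in region mode (undefined)
    mode: str  # "pixel" | "region"


@dataclass(frozen=True)
class ConditionalProbabilities:
    """Percent-scaled rates; ``None`` marks an undefined metric (zero
    denominator, or specificity/accuracy in region mode)."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    dsc: Optional[float]


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    frac_within: float  # fraction of pairs inside the limits


@dataclass(frozen=True)
class AgreementStats:
    pearson_r: float
    icc: float
    icc_ci: tuple[float, float]
    bland_altman: BlandAltman
    areas: np.ndarray  # (n, 2) paired (manual, automatic)


def _check_masks(*masks: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(m, dtype=bool) for m in masks]
    shapes = {m.shape for m in out}
    if len(shapes) != 1:
        raise ValueError(f"mask dimensions differ: {sorted(shapes)}")
    return out


def confusion_pixelwise(pred: np.ndarray, truth: np.ndarray, roi: np.ndarray) -> ConfusionCounts:
    """Pixel counts over the ROI only; tp+fp+tn+fn equals the ROI area."""
    pred, truth, roi = _check_masks(pred, truth, roi)
    if not roi.any():
        raise EmptyRegionError("ROI selects no pixels")
    p, t = pred[roi], truth[roi]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, mode="pixel")


def confusion_regionwise(
    pred: np.ndarray,
    truth: np.ndarray,
    roi: np.ndarray,
    min_overlap_fraction: float = 0.0,
) -> ConfusionCounts:
    """Lesion-level counts inside the ROI (8-connected components).

    A truth component is a TP when predicted pixels cover more than
    ``min_overlap_fraction`` of it (default: any single shared pixel), else
    an FN. A predicted component sharing no pixel with any truth component
    is an FP; one that does overlap is never an FP, however many truth
    lesions it touches. TN is undefined.
    """
    pred, truth, roi = _check_masks(pred, truth, roi)
    if not roi.any():
        raise EmptyRegionError("ROI selects no pixels")
    pred = pred & roi
    truth = truth & roi
    structure = ndi.generate_binary_structure(2, 2)
    t_labels, t_n = ndi.label(truth, structure=structure)
    p_labels, p_n = ndi.label(pred, structure=structure)

    tp = fn = 0
    for lab in range(1, t_n + 1):
        comp = t_labels == lab
        overlap = np.count_nonzero(comp & pred)
        need = max(1, int(np.ceil(min_overlap_fraction * np.count_nonzero(comp))))
        if overlap >= need:
            tp += 1
        else:
            fn += 1
    fp = 0
    for lab in range(1, p_n + 1):
        if not np.count_nonzero((p_labels == lab) & truth):
            fp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=None, mode="region")


def conditional_probabilities(c: ConfusionCounts) -> ConditionalProbabilities:
    """Sensitivity / specificity / accuracy (percent) and DSC from counts.

    Zero-denominator metrics come back as ``None`` rather than 0; region
    mode never reports specificity or accuracy.
    """
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    dsc_den = 2 * c.tp + c.fp + c.fn
    dsc = 2.0 * c.tp / dsc_den if dsc_den > 0 else None
    spec = acc = None
    if c.mode == "pixel" and c.tn is not None:
        spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
        total = c.tp + c.fp + c.tn + c.fn
        acc = 100.0 * (c.tp + c.tn) / total if total > 0 else None
    return ConditionalProbabilities(sensitivity=sens, specificity=spec, accuracy=acc, dsc=dsc)


def _icc_absolute_single(manual: np.ndarray, auto: np.ndarray) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with 95% CI via pingouin's two-way ANOVA decomposition."""
    import pingouin as pg  # deferred: pulls in a sizable stack

    n = len(manual)
    if np.array_equal(manual, auto):
        return 1.0, (1.0, 1.0)  # perfect agreement; the F statistic degenerates
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["manual", "auto"], n),
            "score": np.concatenate([manual, auto]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(df, targets="target", raters="rater", ratings="score")
    row = table[table["Type"] == "ICC(A,1)"].iloc[0]
    ci = row["CI95"] if "CI95" in row.index else row["CI95%"]
    return float(row["ICC"]), (float(ci[0]), float(ci[1]))


def agreement_stats(manual_areas, auto_areas) -> AgreementStats:
    """Pearson r, ICC(2,1) and Bland-Altman limits for paired areas.

    Differences are taken automatic minus manual.

    Raises
    ------
    ValueError
        If fewer than 3 pairs are supplied, the lists differ in length, or
        either list has zero variance (correlation undefined).
    """
    manual = np.asarray(manual_areas, dtype=np.float64)
    auto = np.asarray(auto_areas, dtype=np.float64)
    if manual.ndim != 1 or manual.shape != auto.shape:
        raise ValueError("manual and automatic area lists must be equal-length 1-D")
    n = manual.size
    if n < 3:
        raise ValueError(f"need at least 3 paired areas, got {n}")
    if manual.std() == 0.0 or auto.std() == 0.0:
        raise ValueError("zero variance in an area list; correlation undefined")

    r = float(stats.pearsonr(manual, auto).statistic)
    icc, ci = _icc_absolute_single(manual, auto)

    diffs = auto - manual
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    within = float(np.mean((diffs >= lo) & (diffs <= hi))) if sd > 0 else 1.0
    return AgreementStats(
        pearson_r=r,
        icc=icc,
        icc_ci=ci,
        bland_altman=BlandAltman(mean_diff=mean_diff, loa_low=lo, loa_high=hi, frac_within=within),
        areas=np.column_stack([manual, auto]),
    )


def agreement_plots(stats: AgreementStats, path) -> None:
    """Render a scatter + Bland-Altman figure to ``path`` (requires the
    optional matplotlib dependency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manual, auto = stats.areas[:, 0], stats.areas[:, 1]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(manual, auto, s=18)
    lim = [0, max(manual.max(), auto.max()) * 1.05]
    ax1.plot(lim, lim, "k--", lw=0.8)
    ax1.set_xlabel("manual area (px)")
    ax1.set_ylabel("automatic area (px)")
    ax1.set_title(f"r = {stats.pearson_r:.3f}, ICC = {stats.icc:.3f}")
    means = (manual + auto) / 2
    diffs = auto - manual
    ba = stats.bland_altman
    ax2.scatter(means, diffs, s=18)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax2.axhline(y, color="k", ls=style, lw=0.8)
    ax2.set_xlabel("mean area (px)")
    ax2.set_ylabel("difference, automatic - manual (px)")
    ax2.set_title("Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
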