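"""Automatic threshold selection by Renyi entropy.

For a gray-level probability distribution P_0..P_255 and a cut point t, the
levels split into a low class A1 = {0..t} and a high class A2 = {t+1..255}
with masses P_A1 and P_A2. The order-alpha Renyi entropy of each class is

    H_A1^a(t) = 1/(1-a) * ln( sum_{i<=t} (P_i / P_A1)^a ),

and symmetrically for A2. For each alpha, the component threshold t(alpha)
maximizes H_A1^a(t) + H_A2^a(t); as alpha -> 1 this becomes the Shannon
(maximum-entropy-sum, Kapur) criterion. Three component thresholds are
computed — t(alpha) for one alpha in (0, 1), the Shannon limit, and one
alpha > 1 (entropic correlation) — sorted ascending into t[1] <= t[2] <=
t[3], and blended into a single threshold

    t_c = t[1]*(P(t[1]) + w*b1/4) + t[2]*w*b2/4 + t[3]*(1 - P(t[3]) + w*b3/4)

where P(t) is the cumulative mass up to and including t, w = P(t[3]) -
P(t[1]), and the weights (b1, b2, b3) depend on how far apart the component
thresholds lie: (1,2,1) when |t[1]-t[2]| and |t[2]-t[3]| are both <= 5 or
both > 5, (0,1,3) when only the second gap exceeds 5, (3,1,0) when only the
first does.

Foreground (drusen candidates) is everything strictly brighter than the
chosen threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogramError, EmptyRegionError

__all__ = [
    "RenyiThresholdResult",
    "histogram",
    "renyi_entropy",
    "class_entropies",
    "component_threshold",
    "renyi_threshold",
    "apply_threshold",
    "otsu_threshold",
]

_GAP = 5  # component-threshold gap separating the beta-weight regimes


@dataclass(frozen=True)
class RenyiThresholdResult:
    """Component thresholds (ascending), blend weights and combined cut."""

    t1: int
    t2: int
    t3: int
    beta: tuple[int, int, int]
    omega: float
    t_c: int
    alphas: tuple[float, float, float]

    @property
    def components(self) -> tuple[int, int, int]:
        return (self.t1, self.t2, self.t3)


def histogram(gray: np.ndarray, within: np.ndarray | None = None) -> np.ndarray:
    """Normalized 256-bin histogram of the pixels selected by ``within``.

    Returns a float array p with p[i] >= 0 and sum(p) == 1.

    Raises
    ------
    EmptyRegionError
        If the mask selects no pixels.
    """
    gray = np.asarray(gray)
    vals = gray[np.asarray(within, dtype=bool)] if within is not None else gray.ravel()
    if vals.size == 0:
        raise EmptyRegionError("histogram mask selects no pixels")
    counts = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    return counts / counts.sum()


def _check_histogram(p: np.ndarray) -> np.ndarray:
    """Validate and normalize: raw counts and probabilities are both accepted,
    so every threshold is invariant to scaling the histogram by a constant."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {p.shape}")
    if (p < 0).any():
        raise ValueError("histogram bins must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("histogram carries no mass")
    return p / total


def renyi_entropy(p: np.ndarray, alpha: float) -> float:
    """Order-``alpha`` Renyi entropy of the whole distribution, in nats.

    ``H^a = ln(sum p_i^a) / (1 - a)``; ``alpha == 1`` gives the Shannon
    entropy. A uniform distribution over n levels has entropy ln(n) for
    every order; a degenerate (single-level) distribution has entropy 0.
    """
    p = _check_histogram(p)
    q = p[p > 0]
    if alpha == 1.0:
        return float(-(q * np.log(q)).sum())
    return float(np.log((q**alpha).sum()) / (1.0 - alpha))


def class_entropies(p: np.ndarray, t: int, alpha: float) -> tuple[float, float]:
    """Renyi class entropies (H_A1, H_A2) at cut ``t`` in nats.

    Returns ``(nan, nan)`` when either class carries zero mass (the cut is
    then excluded from any argmax). ``alpha == 1`` computes the Shannon
    limit.
    """
    p = _check_histogram(p)
    if not 0 <= t <= 254:
        raise ValueError(f"cut point must be in [0, 254], got {t}")
    lo, hi = p[: t + 1], p[t + 1 :]
    m1, m2 = lo.sum(), hi.sum()
    if m1 <= 0.0 or m2 <= 0.0:
        return (math.nan, math.nan)

    def _h(cls: np.ndarray, mass: float) -> float:
        q = cls[cls > 0] / mass
        if alpha == 1.0:
            return float(-(q * np.log(q)).sum())
        return float(np.log((q**alpha).sum()) / (1.0 - alpha))

    return (_h(lo, m1), _h(hi, m2))


def _entropy_sum_curve(p: np.ndarray, alpha: float) -> np.ndarray:
    """H_A1^a(t) + H_A2^a(t) for all t in 0..254; -inf where a class is empty.

    Vectorized via cumulative sums; the Shannon limit (alpha == 1) uses the
    identity H_A1 = ln P_A1 - S1(t)/P_A1 with S1(t) = sum_{i<=t} P_i ln P_i.
    """
    c1 = np.cumsum(p)[:255]  # P_A1(t), t = 0..254
    c2 = 1.0 - c1  # P_A2(t)
    valid = (c1 > 0.0) & (c2 > 0.0)
    out = np.full(255, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        if alpha == 1.0:
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            s1 = np.cumsum(plogp)[:255]
            s2 = plogp.sum() - s1
            h1 = np.log(c1) - s1 / c1
            h2 = np.log(c2) - s2 / c2
        else:
            pa = p**alpha
            sa1 = np.cumsum(pa)[:255]
            sa2 = pa.sum() - sa1
            h1 = (np.log(sa1) - alpha * np.log(c1)) / (1.0 - alpha)
            h2 = (np.log(sa2) - alpha * np.log(c2)) / (1.0 - alpha)
    out[valid] = (h1 + h2)[valid]
    return out


def component_threshold(p: np.ndarray, alpha: float) -> int:
    """argmax_t of the class-entropy sum; ties resolve to the smallest t.

    ``alpha == 1`` runs the Shannon/maximum-entropy-sum criterion directly
    rather than a numerical limit.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied (no valid cut exists).
    """
    p = _check_histogram(p)
    if np.count_nonzero(p) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    curve = _entropy_sum_curve(p, float(alpha))
    if not np.isfinite(curve).any():
        raise DegenerateHistogramError("no cut point leaves both classes nonempty")
    return int(np.argmax(curve))  # first maximum = smallest t


def _beta_weights(t_sorted: tuple[int, int, int]) -> tuple[int, int, int]:
    d12 = abs(t_sorted[0] - t_sorted[1])
    d23 = abs(t_sorted[1] - t_sorted[2])
    if d12 <= _GAP and d23 <= _GAP:
        return (1, 2, 1)
    if d12 > _GAP and d23 > _GAP:
        return (1, 2, 1)
    if d12 <= _GAP:  # d23 > GAP
        return (0, 1, 3)
    return (3, 1, 0)  # d12 > GAP, d23 <= GAP


def renyi_threshold(
    p: np.ndarray, alpha_low: float = 0.5, alpha_high: float = 2.0
) -> RenyiThresholdResult:
    """Three-component Renyi threshold with the gap-dependent blend.

    Computes t(alpha_low), the Shannon-limit threshold and t(alpha_high),
    sorts them ascending, and combines them as described in the module
    docstring. The combined cut is rounded half-up to an integer gray level.
    """
    if not 0.0 < alpha_low < 1.0:
        raise ValueError(f"alpha_low must lie in (0, 1), got {alpha_low}")
    if alpha_high <= 1.0:
        raise ValueError(f"alpha_high must exceed 1, got {alpha_high}")
    p = _check_histogram(p)
    ts = sorted(
        (
            component_threshold(p, alpha_low),
            component_threshold(p, 1.0),
            component_threshold(p, alpha_high),
        )
    )
    t1, t2, t3 = (int(t) for t in ts)
    cum = np.cumsum(p)
    p1, p3 = float(cum[t1]), float(cum[t3])
    omega = p3 - p1
    beta = _beta_weights((t1, t2, t3))
    b1, b2, b3 = beta
    tc = (
        t1 * (p1 + 0.25 * omega * b1)
        + 0.25 * t2 * omega * b2
        + t3 * (1.0 - p3 + 0.25 * omega * b3)
    )
    t_c = int(np.clip(np.floor(tc + 0.5), 0, 255))
    return RenyiThresholdResult(
        t1=t1, t2=t2, t3=t3, beta=beta, omega=omega, t_c=t_c,
        alphas=(float(alpha_low), 1.0, float(alpha_high)),
    )


def apply_threshold(gray: np.ndarray, t: int, within: np.ndarray | None = None) -> np.ndarray:
    """Binarize: true where intensity > t (and inside ``within`` if given)."""
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    mask = np.asarray(gray) > t
    if within is not None:
        mask &= np.asarray(within, dtype=bool)
    return mask


def otsu_threshold(p: np.ndarray) -> int:
    """Between-class-variance maximizing threshold (baseline method).

    Ties resolve to the smallest t; cuts leaving a class empty are skipped.
    """
    p = _check_histogram(p)
    if np.count_nonzero(p) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)[:255]
    w1 = 1.0 - w0
    m0cum = np.cumsum(p * levels)[:255]
    mu_total = float((p * levels).sum())
    valid = (w0 > 0.0) & (w1 > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0cum / w0
        mu1 = (mu_total - m0cum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~valid] = -np.inf
    if not np.isfinite(var_between).any():
        raise DegenerateHistogramError("no cut point leaves both classes nonempty")
    return int(np.argmax(var_between))
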