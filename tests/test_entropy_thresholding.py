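import math

import numpy as np
import pytest

from druscan.entropy_thresholding import (
    _beta_weights,
    apply_threshold,
    class_entropies,
    component_threshold,
    histogram,
    otsu_threshold,
    renyi_threshold,
)
from druscan.errors import DegenerateHistogramError, EmptyRegionError
from conftest import random_histogram


# ---------------------------------------------------------------- oracles
def oracle_entropy_sum(p, t, alpha):
    """Direct, loop-based transcription of the class-entropy sum."""
    pa1 = sum(p[: t + 1])
    pa2 = sum(p[t + 1 :])
    if pa1 <= 0 or pa2 <= 0:
        return -math.inf

    def renyi(cls, mass):
        if alpha == 1.0:
            return -sum(q / mass * math.log(q / mass) for q in cls if q > 0)
        return math.log(sum((q / mass) ** alpha for q in cls if q > 0)) / (1 - alpha)

    return renyi(p[: t + 1], pa1) + renyi(p[t + 1 :], pa2)


def oracle_component_threshold(p, alpha):
    """Exhaustive argmax over all 255 cut points, smallest-t ties."""
    vals = [oracle_entropy_sum(p, t, alpha) for t in range(255)]
    best = max(vals)
    return vals.index(best)


def oracle_combined(p, alpha_low, alpha_high):
    """Independent transcription of the three-threshold blend."""
    ts = sorted(
        oracle_component_threshold(p, a) for a in (alpha_low, 1.0, alpha_high)
    )
    t1, t2, t3 = ts
    d12, d23 = abs(t1 - t2), abs(t2 - t3)
    if (d12 <= 5 and d23 <= 5) or (d12 > 5 and d23 > 5):
        beta = (1, 2, 1)
    elif d12 <= 5:
        beta = (0, 1, 3)
    else:
        beta = (3, 1, 0)
    P = lambda t: sum(p[: t + 1])
    omega = P(t3) - P(t1)
    tc = (
        t1 * (P(t1) + omega * beta[0] / 4)
        + t2 * omega * beta[1] / 4
        + t3 * (1 - P(t3) + omega * beta[2] / 4)
    )
    return int(math.floor(tc + 0.5))


def bimodal_histogram(modes=(60, 180), sigma=10.0, n=10**6):
    """Finite-count histogram of a well-separated two-mode image."""
    levels = np.arange(256)
    dens = sum(np.exp(-((levels - m) ** 2) / (2 * sigma**2)) for m in modes)
    counts = np.round(n * dens / dens.sum())
    return counts / counts.sum()


# ---------------------------------------------------------------- histogram
class TestHistogram:
    def test_two_level_region(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        p = histogram(img)
        assert p[0] == 0.5 and p[255] == 0.5 and p[1:255].sum() == 0

    def test_uniform_region(self):
        p = histogram(np.full((3, 3), 7, dtype=np.uint8))
        assert p[7] == 1.0

    def test_mask_restriction_and_normalization(self, rng):
        img = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        mask = rng.random((30, 30)) < 0.4
        p = histogram(img, mask)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(
            np.flatnonzero(p), np.unique(img[mask])
        )

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            histogram(np.zeros((4, 4), dtype=np.uint8), np.zeros((4, 4), dtype=bool))


# ---------------------------------------------------------------- entropies
class TestClassEntropies:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_degenerate_classes_have_zero_entropy(self, alpha):
        p = np.zeros(256)
        p[0] = p[255] = 0.5
        h1, h2 = class_entropies(p, 0, alpha)
        assert h1 == pytest.approx(0.0, abs=1e-12)
        assert h2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 2.0])
    def test_uniform_halves_give_ln_128(self, alpha):
        p = np.full(256, 1 / 256)
        h1, h2 = class_entropies(p, 127, alpha)
        assert h1 == pytest.approx(math.log(128), abs=1e-10)
        assert h2 == pytest.approx(math.log(128), abs=1e-10)

    def test_empty_class_is_flagged_undefined(self):
        p = np.zeros(256)
        p[10] = p[20] = 0.5
        h1, h2 = class_entropies(p, 5, 2.0)
        assert math.isnan(h1) and math.isnan(h2)

    @pytest.mark.parametrize("alpha", [0.5, 2.0])
    def test_matches_direct_summation(self, alpha, rng):
        p = np.zeros(256)
        bins = rng.choice(256, 16, replace=False)
        p[bins] = rng.random(16)
        p /= p.sum()
        t = 128
        h1, h2 = class_entropies(p, t, alpha)
        expected = oracle_entropy_sum(list(p), t, alpha)
        assert h1 + h2 == pytest.approx(expected, abs=1e-10)


# ------------------------------------------------------- component threshold
class TestComponentThreshold:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_two_spike_tie_breaks_to_smallest(self, alpha):
        p = np.zeros(256)
        p[50] = p[200] = 0.5
        assert component_threshold(p, alpha) == 50

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_oracle(self, alpha, seed):
        rng = np.random.default_rng(seed)
        p = random_histogram(rng)
        assert component_threshold(p, alpha) == oracle_component_threshold(list(p), alpha)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_bimodal_threshold_falls_between_modes(self, alpha):
        # finite-count histogram of a two-mode image (modes 60/180, sigma 10)
        p = bimodal_histogram()
        assert 80 < component_threshold(p, alpha) < 160

    def test_single_bin_raises(self):
        p = np.zeros(256)
        p[9] = 1.0
        with pytest.raises(DegenerateHistogramError):
            component_threshold(p, 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_shannon_limit_consistency(self, seed):
        rng = np.random.default_rng(seed)
        p = random_histogram(rng)
        t_shannon = component_threshold(p, 1.0)
        for eps in (-1e-6, 1e-6):
            assert abs(component_threshold(p, 1.0 + eps) - t_shannon) <= 1

    def test_scale_invariance(self, rng):
        p = random_histogram(rng)
        counts = p * 987654
        for alpha in (0.5, 1.0, 2.0):
            assert component_threshold(p, alpha) == component_threshold(counts, alpha)


# ------------------------------------------------------------- combined cut
class TestRenyiThreshold:
    def test_collapses_to_identity_when_components_agree(self):
        p = np.zeros(256)
        p[50] = p[200] = 0.5  # every alpha picks t = 50
        res = renyi_threshold(p)
        assert res.components == (50, 50, 50)
        assert res.beta == (1, 2, 1)
        assert res.omega == 0.0
        assert res.t_c == 50

    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((100, 103, 104), (1, 2, 1)),  # both gaps small
            ((100, 110, 120), (1, 2, 1)),  # both gaps large
            ((100, 103, 120), (0, 1, 3)),  # only second gap large
            ((100, 110, 112), (3, 1, 0)),  # only first gap large
            ((100, 105, 110), (1, 2, 1)),  # boundary: gaps exactly 5
            ((100, 106, 112), (1, 2, 1)),  # boundary: gaps exactly 6
        ],
    )
    def test_beta_weight_table(self, triple, expected):
        assert _beta_weights(triple) == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_transcription(self, seed):
        rng = np.random.default_rng(seed)
        p = random_histogram(rng, n_nonzero=int(rng.integers(8, 256)))
        res = renyi_threshold(p)
        assert res.t_c == oracle_combined(list(p), 0.5, 2.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_combined_lies_between_extremes(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = random_histogram(rng, n_nonzero=int(rng.integers(8, 256)))
        res = renyi_threshold(p)
        assert res.t1 <= res.t2 <= res.t3
        assert res.t1 <= res.t_c <= res.t3

    def test_alpha_validation(self):
        p = np.zeros(256)
        p[1] = p[7] = 0.5
        with pytest.raises(ValueError):
            renyi_threshold(p, alpha_low=1.5)
        with pytest.raises(ValueError):
            renyi_threshold(p, alpha_high=0.5)


# ----------------------------------------------------------- apply / otsu
class TestApplyThreshold:
    def test_max_threshold_empties_mask(self, rng):
        img = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        assert not apply_threshold(img, 255).any()

    def test_zero_threshold_keeps_positive_region(self):
        img = np.full((6, 6), 9, dtype=np.uint8)
        within = np.zeros((6, 6), dtype=bool)
        within[:3] = True
        assert np.array_equal(apply_threshold(img, 0, within), within)

    def test_strictly_greater(self):
        img = np.array([[5, 6]], dtype=np.uint8)
        assert np.array_equal(apply_threshold(img, 5), np.array([[False, True]]))


class TestOtsu:
    def test_two_spike_tie_breaks_to_smallest(self):
        p = np.zeros(256)
        p[50] = p[200] = 0.5
        assert otsu_threshold(p) == 50

    def test_bimodal_threshold_between_modes(self):
        assert 80 < otsu_threshold(bimodal_histogram()) < 160

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_variance_argmax(self, seed):
        rng = np.random.default_rng(seed)
        p = random_histogram(rng)
        levels = np.arange(256)
        best, best_t = -1.0, 0
        for t in range(255):
            w0 = p[: t + 1].sum()
            w1 = 1 - w0
            if w0 <= 0 or w1 <= 0:
                continue
            mu0 = (p[: t + 1] * levels[: t + 1]).sum() / w0
            mu1 = (p[t + 1 :] * levels[t + 1 :]).sum() / w1
            v = w0 * w1 * (mu0 - mu1) ** 2
            if v > best:
                best, best_t = v, t
        assert otsu_threshold(p) == best_t
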