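"""Similarity/concordance statistics vs hand values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleuravol import (
    BinaryMask,
    bland_altman,
    correlate_scores,
    lin_ccc,
    paired_wilcoxon,
    pixel_similarity,
    visual_extent_score,
)
from pleuravol.evalstats import VisualScore


def oracle_confusion(pred, gt):
    """Literal per-pixel loop over the confusion matrix."""
    tp = fp = fn = tn = 0
    for p, g in zip(np.ravel(pred), np.ravel(gt)):
        if p and g:
            tp += 1
        elif p:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestPixelSimilarity:
    def test_hand_counts(self):
        gt = np.zeros((3, 4), dtype=int)
        gt.ravel()[:6] = 1
        pred = np.zeros((3, 4), dtype=int)
        pred.ravel()[3:7] = 1  # |pred|=4, overlap=3
        rep = pixel_similarity(BinaryMask(pred), BinaryMask(gt))
        assert rep.dice == pytest.approx(0.6)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.5)

    def test_perfect_prediction(self):
        m = BinaryMask((np.random.default_rng(0).random((8, 8)) < 0.4).astype(int))
        rep = pixel_similarity(m, m)
        assert (rep.dice, rep.balanced_accuracy, rep.recall, rep.precision) == (1, 1, 1, 1)

    def test_predict_everything(self):
        gt = BinaryMask((np.random.default_rng(1).random((8, 8)) < 0.4).astype(int))
        rep = pixel_similarity(BinaryMask(np.ones((8, 8), dtype=int)), gt)
        assert rep.recall == 1.0
        assert rep.balanced_accuracy == pytest.approx(0.5)

    def test_empty_empty_convention(self):
        z = BinaryMask(np.zeros((4, 4), dtype=int))
        assert pixel_similarity(z, z).dice == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        preds, gts = [], []
        for _ in range(3):
            preds.append(BinaryMask((rng.random((16, 16)) < 0.3).astype(int)))
            gts.append(BinaryMask((rng.random((16, 16)) < 0.3).astype(int)))
        rep = pixel_similarity(preds, gts)
        tp = fp = fn = tn = 0
        for p, g in zip(preds, gts):
            a, b, c, d = oracle_confusion(p.pixels, g.pixels)
            tp, fp, fn, tn = tp + a, fp + b, fn + c, tn + d
        assert rep.dice == 2 * tp / (2 * tp + fp + fn)
        assert rep.precision == tp / (tp + fp)
        assert rep.recall == tp / (tp + fn)
        assert rep.balanced_accuracy == (tp / (tp + fn) + tn / (tn + fp)) / 2

    def test_mismatched_counts_rejected(self):
        m = BinaryMask(np.zeros((4, 4), dtype=int))
        with pytest.raises(Exception, match="masks"):
            pixel_similarity([m, m], [m])


class TestCCC:
    def test_identity(self):
        ccc, _ = lin_ccc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ccc == pytest.approx(1.0)

    def test_shifted_closed_form(self):
        ccc, _ = lin_ccc([1, 2, 3], [2, 3, 4])
        assert ccc == pytest.approx(4 / 7)

    def test_reversed_is_minus_one(self):
        ccc, _ = lin_ccc([1, 2, 3], [3, 2, 1])
        assert ccc == pytest.approx(-1.0)

    def test_equals_pearson_when_moments_match(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.5, size=50)
        y = (y - y.mean()) / y.std() * x.std() + x.mean()  # match moments
        ccc, _ = lin_ccc(x, y)
        assert ccc == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.random(10)
        y = rng.random(10)
        perm = rng.permutation(10)
        assert lin_ccc(x, y)[0] == pytest.approx(lin_ccc(x[perm], y[perm])[0])

    def test_abs_ccc_bounded_by_abs_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.random(20)
        y = 3 * rng.random(20) + 1
        assert abs(lin_ccc(x, y)[0]) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="undefined|constant"):
            lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.random(30)
        y = x + rng.normal(scale=0.1, size=30)
        ccc, (lo, hi) = lin_ccc(x, y)
        assert lo <= ccc <= hi


class TestBlandAltman:
    def test_identical_series(self):
        assert bland_altman([1.0, 2.0], [1.0, 2.0]) == (0.0, (0.0, 0.0))

    def test_constant_difference(self):
        md, (lo, hi) = bland_altman([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert (md, lo, hi) == (2.0, 2.0, 2.0)

    def test_hand_case_with_unit_sd(self):
        md, (lo, hi) = bland_altman([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert md == pytest.approx(2.0)
        assert lo == pytest.approx(2 - 1.96)
        assert hi == pytest.approx(2 + 1.96)


class TestVisualScore:
    @pytest.mark.parametrize("cats, expected", [((1, 1, 1), 1), ((4, 4, 3), 48), ((2, 3, 1), 6)])
    def test_products(self, cats, expected):
        assert visual_extent_score(*cats) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="thickness_cat"):
            visual_extent_score(5, 1, 1)
        with pytest.raises(ValueError, match="count_cat"):
            VisualScore(1, 1, 4)


class TestCorrelation:
    def test_monotone_pairs(self):
        rho, _ = correlate_scores([1, 2, 3, 4], [2, 4, 9, 11])
        assert rho == pytest.approx(1.0)
        rho, _ = correlate_scores([1, 2, 3, 4], [11, 9, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_coarsened_monotone_function_with_noise(self):
        rng = np.random.default_rng(0)
        vols = rng.uniform(0.5, 20, 60)
        scores = np.digitize(vols + rng.normal(scale=2, size=60), [3, 7, 12]) + 1
        rho, p = correlate_scores(vols, scores)
        assert rho > 0.5
        assert p < 0.001


class TestWilcoxon:
    def test_all_ties_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p = paired_wilcoxon([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_uniform_shift_n10(self):
        v2 = list(range(10))
        v3 = [v + 1 for v in v2]
        _, p = paired_wilcoxon(v2, v3)
        assert p < 0.01  # exact two-sided p = 2/2^10

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(1)
        v2 = rng.random(12)
        v3 = v2 + rng.normal(scale=0.3, size=12)
        _, p1 = paired_wilcoxon(v2, v3)
        _, p2 = paired_wilcoxon(v3, v2)
        assert p1 == pytest.approx(p2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_similarity_metrics_stay_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    pred = BinaryMask((rng.random((8, 8)) < rng.random()).astype(int))
    gt = BinaryMask((rng.random((8, 8)) < rng.random()).astype(int))
    rep = pixel_similarity(pred, gt)
    for v in (rep.dice, rep.balanced_accuracy, rep.recall, rep.precision):
        assert 0.0 <= v <= 1.0
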