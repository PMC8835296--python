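"""Similarity, concordance, correlation and scoring statistics.

2D pixel-similarity metrics are micro-averaged: true/false positive/negative
counts are pooled over all slices before forming ratios, so plaque-free
slices (where per-slice Dice would be 0/0) contribute naturally through
their true negatives, and one number summarises an entire test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ct_io import BinaryMask, GeometryError

__all__ = [
    "SimilarityReport",
    "ConcordanceReport",
    "VisualScore",
    "pixel_similarity",
    "dice_from_counts",
    "lin_ccc",
    "bland_altman",
    "visual_extent_score",
    "correlate_scores",
    "paired_wilcoxon",
]


@dataclass(frozen=True)
class SimilarityReport:
    """Pooled 2D pixel-similarity metrics, all in [0, 1]."""

    dice: float
    balanced_accuracy: float
    recall: float
    precision: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "balanced_accuracy": self.balanced_accuracy,
            "recall": self.recall,
            "precision": self.precision,
        }


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-exam 3D volume agreement: Lin's CCC and Bland-Altman."""

    ccc: float
    ccc_ci: tuple[float, float]
    mean_difference: float
    loa: tuple[float, float]
    n: int


@dataclass(frozen=True)
class VisualScore:
    """Ordinal visual extent score: thickness x cumulative-extent x count.

    Thickness categories 1-4 (<2, 2-5, 5-10, >10 mm), extent categories 1-4
    (fractions of the hemithorax perimeter), count categories 1-3 (1, 2, >2
    plaques); the product lies in 1..48.
    """

    thickness_cat: int
    extent_cat: int
    count_cat: int

    def __post_init__(self) -> None:
        if not 1 <= self.thickness_cat <= 4:
            raise ValueError(f"thickness_cat must be in 1..4, got {self.thickness_cat}")
        if not 1 <= self.extent_cat <= 4:
            raise ValueError(f"extent_cat must be in 1..4, got {self.extent_cat}")
        if not 1 <= self.count_cat <= 3:
            raise ValueError(f"count_cat must be in 1..3, got {self.count_cat}")

    @property
    def score(self) -> int:
        return self.thickness_cat * self.extent_cat * self.count_cat


def _ratio(num: float, den: float) -> float:
    """num/den with the empty-denominator convention -> 1 (nothing to miss)."""
    return float(num / den) if den > 0 else 1.0


def dice_from_counts(tp: int, fp: int, fn: int) -> float:
    return _ratio(2 * tp, 2 * tp + fp + fn)


def pixel_similarity(
    pred: Sequence[BinaryMask] | BinaryMask, gt: Sequence[BinaryMask] | BinaryMask
) -> SimilarityReport:
    """Pooled Dice, balanced accuracy, recall and precision over slice sets.

    Counts are accumulated over every pixel of every slice of every mask in
    the two matched sequences; the empty/empty pooled case returns 1 for all
    overlap metrics by convention.
    """
    preds = [pred] if isinstance(pred, BinaryMask) else list(pred)
    gts = [gt] if isinstance(gt, BinaryMask) else list(gt)
    if len(preds) != len(gts):
        raise GeometryError(f"{len(preds)} predicted vs {len(gts)} ground-truth masks")
    tp = fp = fn = tn = 0
    for p, g in zip(preds, gts):
        if p.pixels.shape != g.pixels.shape:
            raise GeometryError(f"mask shapes differ: {p.pixels.shape} vs {g.pixels.shape}")
        pb = p.pixels.astype(bool)
        gb = g.pixels.astype(bool)
        tp += int(np.count_nonzero(pb & gb))
        fp += int(np.count_nonzero(pb & ~gb))
        fn += int(np.count_nonzero(~pb & gb))
        tn += int(np.count_nonzero(~pb & ~gb))
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    return SimilarityReport(
        dice=dice_from_counts(tp, fp, fn),
        balanced_accuracy=(recall + specificity) / 2.0,
        recall=recall,
        precision=_ratio(tp, tp + fp),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def lin_ccc(x: Sequence[float], y: Sequence[float], alpha: float = 0.05):
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ccc = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2) with population
    (n-denominator) moments — the standard Lin definition.  The CI uses the
    Fisher z-transform with SE 1/sqrt(n - 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    vx, vy = x.var(), y.var()  # population moments
    mx, my = x.mean(), y.mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both inputs constant with equal means")
    ccc = float(2.0 * ((x - mx) * (y - my)).mean() / denom)
    if n > 3 and abs(ccc) < 1:
        z = np.arctanh(ccc)
        se = 1.0 / np.sqrt(n - 3)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    else:
        ci = (ccc, ccc)
    return ccc, ci


def bland_altman(x: Sequence[float], y: Sequence[float]):
    """Mean difference and 95% limits of agreement (mean +/- 1.96 sample SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return md, (md - 1.96 * sd, md + 1.96 * sd)


def concordance(ai: Sequence[float], gt: Sequence[float]) -> ConcordanceReport:
    """Bundle CCC and Bland-Altman for per-exam AI vs reference volumes."""
    ccc, ci = lin_ccc(ai, gt)
    md, loa = bland_altman(ai, gt)
    return ConcordanceReport(ccc=ccc, ccc_ci=ci, mean_difference=md, loa=loa, n=len(list(ai)))


def visual_extent_score(thickness_cat: int, extent_cat: int, count_cat: int) -> int:
    """Plain integer product of the three ordinal categories (range 1..48)."""
    return VisualScore(thickness_cat, extent_cat, count_cat).score


def correlate_scores(volumes: Sequence[float], scores: Sequence[int]):
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    volumes = np.asarray(volumes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if volumes.shape != scores.shape:
        raise ValueError("volumes and scores must have equal length")
    res = stats.spearmanr(volumes, scores)
    return float(res.statistic), float(res.pvalue)


def paired_wilcoxon(v2: Sequence[float], v3: Sequence[float]):
    """Two-sided Wilcoxon signed-rank test on paired volumes.

    Zero differences are dropped (the classical convention); if every pair is
    tied the test is degenerate and (0.0, 1.0) is returned with a warning.
    """
    v2 = np.asarray(v2, dtype=float)
    v3 = np.asarray(v3, dtype=float)
    if v2.shape != v3.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(v2 == v3):
        warnings.warn("all paired differences are zero; signed-rank test degenerate, p = 1")
        return 0.0, 1.0
    res = stats.wilcoxon(v2, v3, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
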