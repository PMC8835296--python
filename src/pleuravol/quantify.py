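"""From probability maps to plaque/calcified masks, mL volumes and
longitudinal change statistics.

Calcified plaque is the subset of the plaque mask at or above 100 HU.  On
the MIP path the slab image itself supplies the HU values: maximum-intensity
projection preserves maxima, so a calcified voxel keeps HU >= 100 after
projection.  Both thresholds (probability 0.5, 100 HU) are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ct_io import BinaryMask, CTVolume, GeometryError
from .evalstats import paired_wilcoxon
from .mip import MIPStack, compute_mip, native_mask_volume_ml, slab_mask_volume_ml
from .segnet import ModelWeights, predict

logger = logging.getLogger(__name__)

__all__ = [
    "PlaqueQuant",
    "LongitudinalResult",
    "binarize",
    "split_calcified",
    "quantify_exam",
    "longitudinal_compare",
]

PROB_THRESHOLD = 0.5
CALC_HU_THRESHOLD = 100.0


@dataclass(frozen=True)
class PlaqueQuant:
    """Per-exam plaque volumetrics in mL."""

    exam_id: str
    participant_id: str
    round: int
    pp_volume_ml: float
    calc_volume_ml: float
    source: str  # "native" | "mip"

    def __post_init__(self) -> None:
        if not 0 <= self.calc_volume_ml <= self.pp_volume_ml + 1e-9:
            raise ValueError(
                f"calcified volume {self.calc_volume_ml} must lie in [0, pp volume {self.pp_volume_ml}]"
            )
        if self.source not in ("native", "mip"):
            raise ValueError(f"source must be 'native' or 'mip', got {self.source!r}")


@dataclass(frozen=True)
class LongitudinalResult:
    """Round-2 to round-3 volume change across participants."""

    pairs: tuple[tuple[str, float, float], ...]  # (participant, V2, V3)
    median_difference_ml: float
    difference_ci: tuple[float, float]
    median_percent_increase: float
    percent_ci: tuple[float, float]
    p_value: float
    n_excluded_zero_baseline: int


def binarize(prob: np.ndarray, threshold: float = PROB_THRESHOLD) -> BinaryMask:
    """Positive where probability >= threshold (inclusive); idempotent."""
    prob = np.asarray(prob)
    return BinaryMask((prob >= threshold).astype(np.uint8))


def split_calcified(
    mask: BinaryMask, image: np.ndarray, hu_threshold: float = CALC_HU_THRESHOLD
) -> BinaryMask:
    """Calcified subset: mask AND (HU >= threshold, inclusive)."""
    image = np.asarray(image)
    if mask.pixels.shape != image.shape:
        raise GeometryError(f"mask {mask.pixels.shape} vs image {image.shape}")
    return BinaryMask((mask.pixels.astype(bool) & (image >= hu_threshold)).astype(np.uint8), source=mask.source)


def quantify_exam(
    vol: CTVolume,
    weights: ModelWeights,
    source: str = "mip",
    mip_thickness_mm: float = 5.0,
    prob_threshold: float = PROB_THRESHOLD,
    hu_threshold: float = CALC_HU_THRESHOLD,
) -> PlaqueQuant:
    """Fully automated per-exam quantification: predict -> binarize ->
    calcification split -> volumes in mL.

    ``source="mip"`` runs inference on 5 mm thin-MIP slabs and converts slab
    areas with true slab thicknesses; ``source="native"`` runs slice-by-slice
    on the native volume.
    """
    if source == "mip":
        stack = compute_mip(vol, mip_thickness_mm)
        probs = predict(stack.slabs, weights)
        pp = binarize(probs, prob_threshold)
        calc = split_calcified(pp, stack.slabs, hu_threshold)
        pp_ml = slab_mask_volume_ml(pp, stack)
        calc_ml = slab_mask_volume_ml(calc, stack)
    elif source == "native":
        probs = predict(vol.voxels, weights)
        pp = binarize(probs, prob_threshold)
        calc = split_calcified(pp, vol.voxels, hu_threshold)
        pp_ml = native_mask_volume_ml(pp, vol)
        calc_ml = native_mask_volume_ml(calc, vol)
    else:
        raise ValueError(f"source must be 'mip' or 'native', got {source!r}")
    return PlaqueQuant(
        exam_id=vol.exam_id,
        participant_id=vol.participant_id,
        round=vol.round,
        pp_volume_ml=pp_ml,
        calc_volume_ml=calc_ml,
        source=source,
    )


def _bootstrap_median_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int = 2000, alpha: float = 0.05
) -> tuple[float, float]:
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    meds = np.median(values[idx], axis=1)
    lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def longitudinal_compare(
    quants: Sequence[PlaqueQuant],
    which: str = "pp",
    seed: int = 0,
    n_boot: int = 2000,
) -> LongitudinalResult:
    """Paired round-2 vs round-3 comparison across participants.

    Computes the median volume difference and median percent increase with
    seeded percentile-bootstrap 95% CIs, and the two-sided Wilcoxon
    signed-rank p-value.  Participants with a zero round-2 volume are
    excluded from the percent-increase summary (logged) but kept in the
    absolute differences.  Every participant must contribute exactly one
    round-2 and one round-3 quantification.
    """
    if which not in ("pp", "calc"):
        raise ValueError(f"which must be 'pp' or 'calc', got {which!r}")
    attr = "pp_volume_ml" if which == "pp" else "calc_volume_ml"
    per: dict[str, dict[int, float]] = {}
    for q in quants:
        per.setdefault(q.participant_id, {})
        if q.round in per[q.participant_id]:
            raise ValueError(f"participant {q.participant_id} has duplicate round {q.round}")
        per[q.participant_id][q.round] = getattr(q, attr)
    bad = sorted(p for p, r in per.items() if set(r) != {2, 3})
    if bad:
        raise ValueError(f"participants without a complete round-2/round-3 pair: {bad}")
    ids = sorted(per)  # participant order must not matter
    v2 = np.array([per[p][2] for p in ids])
    v3 = np.array([per[p][3] for p in ids])
    diffs = v3 - v2
    rng = np.random.default_rng(seed)
    diff_ci = _bootstrap_median_ci(diffs, rng, n_boot)
    nonzero = v2 > 0
    n_excl = int((~nonzero).sum())
    if n_excl:
        logger.info("excluding %d participants with zero baseline volume from percent increase", n_excl)
    if nonzero.any():
        pct = 100.0 * diffs[nonzero] / v2[nonzero]
        pct_ci = _bootstrap_median_ci(pct, rng, n_boot)
        pct_med = float(np.median(pct))
    else:
        pct_med, pct_ci = float("nan"), (float("nan"), float("nan"))
    _, p = paired_wilcoxon(v2, v3)
    return LongitudinalResult(
        pairs=tuple((p_, float(a), float(b)) for p_, a, b in zip(ids, v2, v3)),
        median_difference_ml=float(np.median(diffs)),
        difference_ci=diff_ci,
        median_percent_increase=pct_med,
        percent_ci=pct_ci,
        p_value=float(p),
        n_excluded_zero_baseline=n_excl,
    )
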