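"""End-to-end desk-scale experiment workflows.

These functions reproduce the full evaluation protocol on synthetic phantom
cohorts at CPU-friendly problem sizes: train the small U-Net profile on
sampled thorax slabs, then measure pooled 2D similarity, calcified-subset
similarity, per-exam 3D volume concordance, repeat-inference reproducibility
and longitudinal volume progression.  Everything is driven by a single seed.

Problem sizes (100 training exams of 4 slabs each, 14 held-out exams, 20
longitudinal participants) keep a full run within a few CPU-minutes while
leaving enough data for stable pooled metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ct_io import BinaryMask
from .evalstats import SimilarityReport, lin_ccc, pixel_similarity
from .mip import MIPStack, compute_mip, project_mask, slab_mask_volume_ml
from .phantom import generate_exam, generate_longitudinal_pair, sample_spec
from .quantify import LongitudinalResult, binarize, longitudinal_compare, quantify_exam, split_calcified
from .segnet import ModelWeights, TrainConfig, build_and_train, predict

__all__ = ["DeskBenchmark", "train_desk_model", "evaluate_desk_model", "run_desk_benchmark", "run_longitudinal_benchmark"]

MIP_THICKNESS_MM = 5.0


@dataclass
class DeskBenchmark:
    """Results of the desk-scale train/evaluate protocol."""

    weights: ModelWeights
    similarity: SimilarityReport
    calc_similarity: SimilarityReport
    ccc: float
    ccc_ci: tuple[float, float]
    repeat_dice: float
    ai_volumes_ml: list[float]
    gt_volumes_ml: list[float]
    n_test_slabs: int = 0
    n_repeat_slabs: int = 0


def _sample_stacks(rng: np.random.Generator, n_exams: int, prefix: str):
    """Sample exams and return (stack, slab ground-truth mask) pairs."""
    out = []
    for i in range(n_exams):
        spec = sample_spec(rng, participant_id=f"{prefix}{i}")
        vol, pp, _calc = generate_exam(spec)
        stack = compute_mip(vol, MIP_THICKNESS_MM)
        out.append((stack, project_mask(pp, stack)))
    return out


def train_desk_model(seed: int, n_train_exams: int = 100, **config_overrides) -> ModelWeights:
    """Sample a training cohort and fit the desk-profile U-Net, all seeded."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    train = _sample_stacks(rng, n_train_exams, "tr")
    pairs = [(st.slabs[i], gt.pixels[i]) for st, gt in train for i in range(st.n_slabs)]
    cfg = TrainConfig.desk(seed=seed, **config_overrides)
    return build_and_train(pairs, cfg)


def evaluate_desk_model(
    weights: ModelWeights, seed: int, n_test_exams: int = 14
) -> DeskBenchmark:
    """Held-out evaluation mirroring the test-cohort protocol.

    Pooled 2D similarity over all held-out slabs, the same restricted to the
    calcified subset (both masks intersected with the >= 100 HU rule), Lin's
    CCC between per-exam AI and ground-truth slab volumes, and the Dice
    between two repeated inference runs on the same stack.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    test = _sample_stacks(rng, n_test_exams, "te")
    preds: list[BinaryMask] = []
    gts: list[BinaryMask] = []
    cpreds: list[BinaryMask] = []
    cgts: list[BinaryMask] = []
    ai_v: list[float] = []
    gt_v: list[float] = []
    for stack, gt in test:
        pm = binarize(predict(stack.slabs, weights))
        preds.append(pm)
        gts.append(gt)
        cpreds.append(split_calcified(pm, stack.slabs))
        cgts.append(split_calcified(gt, stack.slabs))
        ai_v.append(slab_mask_volume_ml(pm, stack))
        gt_v.append(slab_mask_volume_ml(gt, stack))
    rep_slabs = np.concatenate([st.slabs for st, _ in test[:5]])  # ~20-slab stack
    rep1 = binarize(predict(rep_slabs, weights))
    rep2 = binarize(predict(rep_slabs, weights))
    repeat = pixel_similarity(rep1, rep2)
    ccc, ci = lin_ccc(ai_v, gt_v)
    return DeskBenchmark(
        weights=weights,
        similarity=pixel_similarity(preds, gts),
        calc_similarity=pixel_similarity(cpreds, cgts),
        ccc=ccc,
        ccc_ci=ci,
        repeat_dice=repeat.dice,
        ai_volumes_ml=ai_v,
        gt_volumes_ml=gt_v,
        n_test_slabs=sum(st.n_slabs for st, _ in test),
        n_repeat_slabs=rep_slabs.shape[0],
    )


def run_desk_benchmark(seed: int, n_train_exams: int = 100, n_test_exams: int = 14) -> DeskBenchmark:
    weights = train_desk_model(seed, n_train_exams)
    return evaluate_desk_model(weights, seed, n_test_exams)


def run_longitudinal_benchmark(
    weights: ModelWeights,
    seed: int,
    n_participants: int = 20,
    growth_factor: float = 1.7,
) -> LongitudinalResult:
    """Round-2/round-3 cohort with known plaque growth, quantified end-to-end.

    Each participant's round-3 plaques are scaled for a ground-truth volume
    ratio of ``growth_factor``; the fully automated pipeline (inference,
    thresholds, voxel volumetrics) then recovers the median percent increase
    and the paired signed-rank p-value.  Quantification runs on native
    slices: at desk scale an exam spans only a handful of 5 mm slabs, so
    slab-geometry volumes quantize axial change too coarsely for a
    per-participant change ratio, while the native path measures it voxel
    by voxel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    quants = []
    for i in range(n_participants):
        spec = sample_spec(rng, participant_id=f"L{i}")
        (v2, _, _), (v3, _, _) = generate_longitudinal_pair(spec, growth_factor)
        quants.append(quantify_exam(v2, weights, source="native"))
        quants.append(quantify_exam(v3, weights, source="native"))
    return longitudinal_compare(quants, which="pp", seed=seed)
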