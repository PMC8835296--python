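# Methods

## Problem and pipeline

Pleural plaques — localized hyaline-fibrosis thickenings of the parietal
pleura, the most common CT manifestation of occupational asbestos exposure —
have lacked a consensual quantitative measure; visual scores are ordinal and
only moderately reproducible. `pleuravol` implements a fully automated
volumetric pipeline:

1. **Thin MIP preprocessing.** The native axial stack (1–1.25 mm slices) is
   reduced to non-overlapping maximum-intensity slabs of nominal 5 mm
   (`round(thickness/dz)` consecutive slices; a 300-slice exam becomes 60
   slabs). MIP preserves the brightest structure along z: plaques attenuate
   above the lung and extrapleural fat that surround them, so they survive
   projection, while the 5 mm limit keeps ribs from overlapping them.
   Slabs are non-overlapping by design — a sliding window would not reduce
   the slice count. The trailing partial slab is kept and weighted by its
   true thickness (`n_slices_in_slab × dz`), conserving scanned extent.
2. **2D U-Net segmentation.** One input channel (the CT image), encoder
   filter counts doubling from 24 per level (24, 48, …), two 3×3
   convolutions + ReLU per block, 2×2 max-pooling, dropout after each
   descending-path block, bilinear ×2 upsampling with concatenation skip
   connections in the decoder, and a final 1×1 convolution with sigmoid
   output. Loss is the sum of binary cross-entropy and soft Dice loss,

       L = L_BCE + L_DL,
       L_BCE = −mean[y·log ŷ + (1−y)·log(1−ŷ)],
       L_DL  = 1 − (2Σyŷ + 1)/(Σy + Σŷ + 1),

   a standard combination for imbalanced structures: BCE calibrates pixels,
   the Dice term rewards overlap of a small foreground, and the +1
   smoothing makes empty/empty a perfect score. Training uses Adam
   (lr 1e-3), batch size 1, and horizontal/vertical flip augmentation (the
   same flip applied to image and mask). Inference is slice-by-slice with
   dropout off, so repeated runs are bit-identical.
3. **Thresholds and volumetrics.** Probability maps are binarized at 0.5
   (inclusive). The calcified subset is the plaque mask intersected with
   HU ≥ 100 (inclusive); on the MIP path the slab image itself supplies the
   HU values, which is sound because max-projection can only raise a
   voxel's displayed HU — a calcified voxel keeps HU ≥ 100. Volumes in mL
   are positive-pixel counts × pixel area × slice (or true slab) thickness.
4. **Evaluation statistics.** 2D similarity (Dice, balanced accuracy,
   precision, recall) is micro-averaged from pooled TP/FP/FN/TN counts over
   all slices — per-slice averaging cannot represent plaque-free slices,
   whereas pooled counts handle them naturally. Per-exam volume agreement
   uses Lin's concordance correlation coefficient with population moments,
   `2·cov/(var_x + var_y + (mean_x − mean_y)²)`, with a Fisher-z CI
   (SE 1/√(n−3); the CCC literature offers several CI constructions, this
   is the simplest defensible one), plus Bland–Altman mean difference and
   limits of agreement (mean ± 1.96 × sample SD). Correlation with ordinal
   visual extent scores (thickness category × cumulative-extent category ×
   plaque-count category, range 1..48) uses Spearman's rho with average
   ranks for ties. Longitudinal change uses the median paired difference
   and median percent increase with seeded percentile-bootstrap 95% CIs
   (2000 resamples) and a two-sided Wilcoxon signed-rank test (zero
   differences dropped; an all-tied cohort degenerates to p = 1 with a
   warning). Participants with zero baseline volume are excluded from the
   percent-increase summary (logged) but kept in absolute differences.

## The numpy network core

No deep-learning framework is used: `pleuravol.nn` is a compact
hand-written implementation — im2col 3×3 convolutions executed as BLAS
matmuls, exact-adjoint separable bilinear upsampling, argmax-routed pooling
gradients, inverted dropout and Adam — with backward passes verified
against finite differences in the test suite. This keeps the package
dependency-light and every computation deterministic given its seed. The
"trilinear" upsampling sometimes quoted for 2D decoders is implemented as
bilinear interpolation, its 2D restriction.

Intensities are normalised to [0, 1] through a fixed [−1000, +1000] HU
window before entering the network, so the 100 HU calcification semantics
are identical across exams; no per-exam statistics are involved.

## Synthetic thorax phantom

Clinical CT cohorts of asbestos-exposed workers are not redistributable, so
every stage is exercised on a generated phantom with exact ground truth.
An axial section is modelled as nested ellipses: body at +40 HU, two lungs
at −800 HU, a 3 mm extrapleural fat lining at −100 HU on the inner chest
wall, short +700 HU rib arcs near the outer wall, and plaques as crescent
shells hugging the lung boundary — soft plaque at +60 HU, calcified at
+400 HU — rasterized deterministically from arc centre/extent, thickness
in mm, axial slice span, laterality and a calcified flag. Additive
Gaussian noise (SD 10 HU, truncated at ±3σ so per-tissue HU ranges remain
strictly assertable) is seeded per exam. Only the soft < 100 ≤ calcified
HU split is externally constrained; the other tissue values are plausible
round numbers. The fat lining matters: it reproduces the clinically
discriminating property that plaques attenuate far above the structures
that actually border them at the pleural interface (aerated lung,
extrapleural fat). Without it the phantom would present plaque directly on
muscle-density body at a 20 HU contrast — a harder task than the real one.

Ground-truth volumes come from the rasterized masks themselves, so the
generator's bookkeeping and brute-force voxel counting agree exactly.

**Desk scale.** The default experiment profile uses a miniature 64 mm
thorax on a 64×64 grid at 1 mm pixels and 20 slices (4 slabs) — miniature
rather than down-sampled, so 2.5–8 mm plaques stay spatially resolved.
Cohorts are sampled with 1–5 plaques per exam, arc extents 40–200°
(mirroring visual-extent categories up to more than half the hemithorax
perimeter), thickness 2.5–8 mm, 50% calcified, giving ground-truth burdens
spanning roughly an order of magnitude (~0.5–15 mL).

**Longitudinal growth.** Round-3 plaques grow along the pleural surface:
arc extent and axial span are scaled, thickness is kept. The scale factor
is calibrated by bisection on exact rasterized voxel counts so that the
ground-truth volume ratio equals the requested growth factor up to
rasterization granularity. Growth is deliberately placed in dimensions the
voxel grid resolves: sub-voxel thickening cannot be recovered by any
pixel-counting method at phantom resolution, which would confound the
parameter-recovery experiments with a resolution artefact rather than a
property of the method.

**What the phantom does not model.** Partial-volume effects (tissue
boundaries are crisp), beam hardening and streak artefacts, breathing or
cardiac motion, anatomical variability of the chest wall, diaphragmatic or
mediastinal complexity, and other pleural pathology. Passing phantom tests
therefore demonstrates that the pipeline's machinery (projection, training,
thresholds, volumetrics, statistics) is correct and recovers known truth
under clean conditions; it does not certify clinical performance on real
scans, where reported Dice for soft plaques is markedly lower.

## Training profiles

`TrainConfig` defaults to the full-scale settings (512×512, 24 base
filters, depth 5, 200 epochs, dropout 0.5, constant lr). `TrainConfig.desk()`
is the CPU profile used by tests and benchmarks: 64×64, 8 base filters,
depth 3, 25 epochs, dropout 0.05, and a step learning-rate decay (×0.3 at
70% and 90% of epochs). The profile deviates from the full-scale
hyperparameters where scale demands it: at 8-filter capacity a 0.5 dropout
starves the model, and with batch-size-1 Adam a terminal learning-rate
drop is needed for boundary placement to settle within 25 epochs. The
profile is a parameter preset, never a separate code path.

Benchmark problem sizes: 100 training exams (400 slabs), 14 held-out exams
(56 slabs), 20 longitudinal participants — chosen to give stable pooled
metrics in a few CPU-minutes. The longitudinal benchmark quantifies on the
native path: a desk exam spans only ~4 slabs, so slab-quantized volumes
cannot express per-participant change ratios (partial-slab padding
compresses them), while the native path measures change voxel-exactly.
Native-vs-MIP volumetric equivalence is verified separately on
slab-aligned phantoms, where the two paths agree exactly.

## Numerical choices and edge cases

- Probability 0.5 and 100 HU thresholds are inclusive (documented because
  boundary conventions are otherwise invisible).
- BCE predictions are clipped to [1e-7, 1 − 1e-7]; the worst case is finite.
- Pooled similarity ratios use the convention 0/0 → 1 (nothing to miss).
- CCC is undefined (raises) when both inputs are constant with equal means.
- `split_exams` splits at the participant level so both screening rounds of
  a participant land on the same side — the leakage-free design for
  longitudinal data.
- All randomness flows through `numpy.random.Generator` objects derived
  from explicit seeds; the CLI fans one global seed out to per-stage seeds
  via SHA-256, so stages are independently reproducible.

## Known limitations

- The numpy network trains on CPU only; full-scale (512×512, depth 5,
  200 epochs) training is possible but slow — the desk profile is the
  practical envelope for routine runs.
- Plaque instance counting and per-plaque thickness measurement are out of
  scope; visual-score categories are inputs, not computed quantities.
- DICOM series ingestion is not implemented; NIfTI is the on-disk format.
- The phantom's fidelity limits (above) mean clinical claims require real
  annotated cohorts.
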