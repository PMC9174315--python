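# Methods

## Problem and model

`slidemil` predicts a binary patient-level label (the motivating application
is microvascular invasion, MVI, in hepatocellular carcinoma) from pyramidal
histology whole-slide images (WSIs) using only weak supervision: every patch
bag drawn from any slide of a patient inherits that patient's label,
regardless of where — or whether — the evidence appears on that particular
slide. The pipeline is:

1. **Tiling.** Each WSI is divided into non-overlapping 512×512 patches at
   5×/10×/20× (40× is supported for segmentation experiments but excluded
   from the prediction model, where it adds no value). Patches with *over*
   50% background are excluded; a patch at exactly 50% is kept. Background
   is a white-glass HSV rule (saturation < 0.08 and brightness > 0.85,
   both config-exposed); the published criterion behind this stage is not
   specified precisely, so the rule here is a standard stand-in.
2. **Tissue gating.** A patch classifier assigns tumor vs peri-tumor;
   prediction bags are restricted to tumor patches (the configuration that
   wins on data where the discriminative signal lives in the tumor). Patch
   ground truth comes from pixel masks by majority vote (> 50% tumor
   pixels ⇒ tumor). An oracle backend reads the synthetic masks directly
   so MIL results do not depend on segmenter quality.
3. **Bags.** One bag per slide per epoch: a fresh uniform sample of 8 / 32 /
   64 tumor patches at 5× / 10× / 20× (with-replacement padding when a
   slide has fewer, keeping the attention layer's shape fixed).
4. **Attention MIL.** Each patch is embedded by a small CNN; gated
   attention pooling (tanh ⊗ sigmoid gating, softmax over instances, after
   Ilse et al.'s attention-MIL formulation) collapses the bag; a linear
   head scores it. Loss is bag-level binary cross-entropy.
5. **Checkpoint ensembling.** A patient-disjoint fine-tune subset of the
   training pool is scored after every epoch. The overfitting point is the
   first epoch at which the moving-average (window 3) fine-tune loss has
   risen for 3 consecutive epochs; the five checkpoints with the best
   fine-tune AUC strictly before that point form the ensemble (ties break
   toward earlier epochs; if fewer than five epochs precede the rise, all
   epochs become candidates). A bag's score is the arithmetic mean of the
   five members.
6. **Hierarchical scoring.** WSI score = mean of the three magnification
   ensemble scores (a magnification with no tumor patches is skipped and
   flagged); patient score = mean of WSI scores; the patient is called
   positive when the score is ≥ the cutoff (default 0.58, with a score
   exactly at the cutoff counted positive).

## NumPy network

The CNN and attention head are implemented directly in NumPy with
hand-written backprop (verified against numeric gradients to ~1e-7 in the
test suite). Two 3×3 conv blocks (8 then 16 channels), leaky ReLU
(slope 0.1), 2×2 *average* pooling and global average pooling produce a
16-d patch embedding from a 32×32 input — patches are block-averaged from
512×512 down to 32×32 before entering the network, and centered by a
fixed offset of 0.65 (roughly the mean tissue brightness). The centering
and the leaky slope matter: with raw all-positive RGB inputs and per-bag
Adam steps, plain ReLU units drift into the dead regime within a few
epochs and training flatlines at ln 2 — centered inputs plus a leaky
slope keep every unit trainable, which is also what lets the attention
layer specialize onto signal-bearing patches. Average pooling (rather
than max) keeps gradients smooth and the backward pass exact; reflect
padding keeps constant inputs constant, which also makes Grad-CAM on
flat patches well behaved.
Optimization is Adam (lr 3e-3) with one bag per step. All randomness —
init, data order, bag draws — flows from the estimator's `random_state`.
The backbone is pluggable (`AttentionMILClassifier.BACKBONES`); a
pre-trained Inception-style extractor can be registered externally behind
the same forward/backward contract, but none ships with the package.

Because global average pooling follows the last conv layer, Grad-CAM's
gradient-weighted channel sum reduces to a CAM: the map is the ReLU'd
projection of the last conv feature map onto the positive-logit direction,
normalized to [0, 1] and upsampled to 512×512. The Grad-CAM target is the
positive-class logit of the patch scored as a singleton bag.

## Synthetic cohort

The generator emulates exactly the structural features the method depends
on, and nothing more:

* several slides per patient sharing one patient-level label;
* a contiguous elliptical tumor region (default half of the tissue)
  surrounded by peri-tumor tissue, with a white glass margin;
* distinct base textures for tumor (purple, coarse blobs) and peri-tumor
  (pink, fine blobs), identical across classes, so tissue segmentation is
  learnable but carries no label information;
* a class-conditional signal *only* in tumor regions of positive patients:
  a mean color shift plus an extra coarse blob component, both scaled by
  `effect_size` (0 = positives and negatives identically distributed). A
  `signal_fraction < 1` confines the signal to part of the tumor, which is
  how the attention-localization check constructs signal/non-signal
  contrast within positive bags.

It deliberately does **not** model H&E stain realism, nuclei, artifacts, or
scanner noise; passing tests therefore demonstrate that the machinery
recovers a planted, learnable signal under weak supervision — not that the
model would reach any particular accuracy on real histology.

Slides are procedural and rendered lazily. Texture lives on coarse grids
(blob fields at base/8, pixel noise at base/4), so any pyramid level can be
composed directly at its own resolution; level k equals the block-mean of
level k−1 up to clipping and uint8 quantization. A fast reduced-resolution
path (`render_scaled`) composes the 32×-downsampled thumbnails the network
actually consumes without materializing full rasters; it matches the
block-mean of the full render exactly for the smooth content and
statistically (noise drawn at the aggregated resolution with sd scaled by
the aggregation factor) for the pixel noise. The pixel path
(render → tile → HSV filter → block-mean) remains available
(`prepare_features(..., pixel_path=True)`) and the two paths agree to
within the noise floor. Determinism: every slide draws from substreams
keyed by `(seed, patient_id, slide_id)` via SHA-256, so identical
config + seed reproduces bit-identical rasters regardless of render order.

## Reference study conditions

`slidemil.study` pins the desk-scale conditions used by the acceptance
script and tests: 64 patients, 2–4 slides each, prevalence 0.5,
effect size 2.0, tumor fraction 0.5, noise sd 0.05, 8192² base rasters
(40×-equivalent; 8×8 patch grid at 20×, 4×4 at 10×, 2×2 at 5×), split
70/30 by patient with 20% of training patients as the fine-tune set, 12
training epochs. Under these conditions the full pipeline separates
held-out patients essentially perfectly (AUC ≈ 1.0), peri-tumor-only bags
stay at chance, and the tumor-vs-peri-tumor AUC gap is large.

The label-permutation null is reported as the **mean over 5 independent
permutation replicates**. With ~19 held-out patients a single null AUC has
Monte-Carlo sd ≈ 0.13, so one replicate frequently strays far from 0.5 by
chance alone; averaging replicates (sd ≈ 0.06) makes "chance level" a
stable quantity without touching the chance band itself.

## Clinical tissue-limitation simulators

Reducing tissue never changes the scoring formula, only the patch pool.

* **single-WSI / k-WSI:** per patient, k slides sampled without
  replacement (all slides when fewer exist); patient score = mean of the
  sampled WSI scores; 100 iterations, summarized as mean ± sd AUC.
* **needle biopsies:** 1–3 pairwise-disjoint contiguous strips of tumor
  patches placed on the 10× grid of one randomly chosen slide per patient,
  then mapped to the other magnifications' grids covering the same
  physical field; bags are drawn only from strip patches. A core that
  cannot be placed is retried with shorter strips and the patient flagged
  rather than silently dropped. The default strip length is 30 patches at
  10× (≈ 7.9 mm² at 1 µm/px, with `physical_area_mm2` bookkeeping exposed
  so users can match their scanner); the desk-scale synthetic slides have
  4×4 grids at 10×, so the reference study uses strips of 3 patches.

## Evaluation

AUC is the Mann–Whitney pair statistic (ties half-credit), computed via
scikit-learn's trapezoidal ROC. Confidence intervals use the DeLong
structural-components variance with a normal approximation (the CI method
is a package choice; it is stated with every interval). The two-sided
DeLong test is implemented from the structural components (midrank form)
and verified in the tests against R's pROC (`roc.test`, `ci.auc`) to 1e-9
as well as against a subject bootstrap; paired mode includes the
covariance term, unpaired mode sums the two variances. The best-accuracy
cutoff scans midpoints between adjacent sorted unique scores plus two
boundary cutoffs, breaking ties toward the lowest cutoff; confusion
metrics use the ≥-cutoff convention.

## Interpretability

Attention heatmaps map per-patch attention weights (ensemble-averaged) back
onto grid coordinates one cell per patch. Cohort-wide ranking extracts the
top/bottom-4000 patches by raw attention weight by default; the ranking
column is an argument (`score_column`), so weight × bag-score ranking is
a one-line change.
Clustering of ranked patches runs k-means (default 8 clusters) on backbone
feature vectors, with t-SNE/PCA used only for 2-D display; the published
deep-clustering variant this stands in for is outside this package's
scope, and the labelling rule — strictly over 60% of members originating
from positive patients ⇒ positive-related, symmetric for negative, exactly
60% unassigned — is independent of the clustering algorithm.

## Numerical and design choices

* Patch grids use 0-based row-major (grid_row, grid_col) with half-open
  pixel intervals [512·i, 512·(i+1)); partial edge tiles are discarded.
* Missing pyramid levels are synthesized by area-average downsampling from
  the nearest higher level.
* Attention softmax subtracts the max before exponentiation; weights sum
  to 1 within 1e-6 by contract and exactly up to float rounding.
* Identical-instance bags give exactly uniform weights; bag order is
  immaterial up to float addition order (~1e-7 at float32).
* Slide scoring uses one seeded evaluation bag per slide (fixed draw, so
  reruns are identical); fine-tune bags are drawn once per training run
  and reused across epochs for stable checkpoint selection.
* Scores are kept at full float precision in artifacts; display rounds to
  3 decimals.

## Known limitations

* The synthetic texture signal is color/blob-scale based and far easier
  than real histomorphology; absolute AUCs here say nothing about
  clinical performance.
* The NumPy backbone is intentionally tiny; swapping in a pre-trained
  deep extractor is supported by contract but not benchmarked.
* SVS container support requires an external reader; pyramidal TIFF and
  PNG tile directories are the supported formats.
* The biopsy simulator models in-plane contiguous strips only — no needle
  deflection, fragmentation or out-of-plane sampling.
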