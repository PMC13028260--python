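# Methods

This note records the modeling choices, parameter conventions and numerical
decisions behind `mammofuse`, and what the synthetic-data tests do and do not
establish.

## Model

**Local stream.** A staged convolutional encoder in the ConvNeXt idiom: a
patchifying stem (4×4 convolution, stride 4, layer norm), then per stage one
or more blocks of `7×7 depthwise conv → LN → 1×1 expand to 4C → GELU → 1×1
project to C → residual add`, with `LN + 2×2 stride-2 conv` downsampling
between stages. The final-stage map is the local representation `F_L`.
Presets: `tiny` (channels 16→32, input 96×96, total stride 8) and `base`
(channels 128→256→512→1024, input 384×384, total stride 32). Base preserves
the published channel plan and operators but uses one block per stage — the
published stage depths are sized for GPU training and contribute nothing to
the contracts tested here; depth is a preset field and can be raised freely.

**Global stream.** A hierarchical windowed transformer in the SwinV2 idiom:
patch embedding (stride-p convolution + LN), stages of shifted-window
attention blocks, 2×2 patch merging between stages. Window attention uses
scaled cosine similarity `cos(q_i, k_j)/τ + b(i−j)` with a learnable
per-head temperature τ (clamped below at 0.01; init 1.0) and a learnable
relative position bias table indexed by within-window offset (direct table,
not the continuous-MLP variant — identical contract at this scale). Blocks
alternate shift 0 and ⌊M/2⌋; cross-window leakage after the cyclic shift is
prevented by masking token pairs whose true (unwrapped) neighborhoods
differ, verified in the tests against a brute-force per-neighborhood
attention oracle. Zero-norm queries/keys get cosine 0 by a norm clamp.
Post-residual normalization: `x ← LN(x + branch(x))` for both the attention
and MLP branches.

**Fusion (BDCG).** The local map is flattened row-major to tokens; each
stream queries the other through multi-head scaled dot-product
cross-attention (8 heads × d=128 for base, 2 × 16 for tiny; plain softmax
attention — cosine attention is reserved for the global encoder), with
independent linear projections per pathway and role, output projected back
to the query stream's width, residual added, then LN. Both pathways run in
parallel from the raw streams (the refinement equations reference the
unrefined `F_L`, `F_G`). Each refined stream is mean-pooled over its tokens
and concatenated local-first into `Z`; pooling before concatenation is the
only reading consistent with a prototype dimension equal to `C_L + C_G`.
The pre-pool spatial maps are kept for saliency; for display or fused-layer
Grad-CAM the lower-resolution stream is aligned to the higher-resolution
grid by bilinear interpolation.

**Classifier (PASH).** One learnable prototype per class (benign = 0,
malignant = 1), initialized i.i.d. Gaussian (scale 0.05). Posterior:
Student-t kernel on squared Euclidean distances, computed in log space
(normalization holds to 1e-12 for α from 0.5 to 1e6). α defaults to 3.0
fixed; a learnable variant parameterizes α = softplus(raw) with a 1e-6
floor, initialized at 3.0. Loss: cross-entropy on the posteriors (no
auxiliary linear logits — the head replaces the softmax classifier) plus
λ = 0.5 times the clustering pull, the label-weighted mean squared distance
to the own-class prototype (soft MixUp labels weight each class pull by its
mixing mass; no push term — the cross-entropy already repels the wrong
prototype). Exact posterior ties predict class 0 with confidence 0.5 and an
explicit ambiguity flag, keeping evaluation deterministic.

**Grad-CAM.** Channel weights are globally averaged gradients of the class
score; the map is `ReLU(Σ α_k A^k)`, optionally bilinearly upsampled and
max-normalized (zero maps stay zero). The backpropagated score for the
prototype head is the kernel log-odds `log k_c − log k_other`, the analogue
of a pre-softmax logit for a two-class prototype classifier: its gradient
follows the fixed prototype axis `P_c − P_other`, whereas the single-class
log-kernel's gradient direction `P_c − Z` collapses toward noise once Z sits
near its own prototype, degenerating the channel weights. (For a softmax
head the logit itself is used.) Default target layer: the aligned fused map
(the representation actually classified); the `local`/`global` options
target the encoder stage-4 outputs, which are pre-normalization and so
preserve response magnitude. All gradients are validated against finite
differences, both per-operation and end-to-end through the full model.

## Preprocessing and augmentation

CLAHE uses 8×8 tiles with bilinear inter-tile blending and the clip-limit
convention "multiple of the uniform bin height" (default 2.0, 256 bins over
the image's own dynamic range); the image is edge-padded to a tile multiple
and a single-tile configuration with a high clip limit reduces exactly to
global histogram equalization (oracle-tested). A constant image passes
through unchanged. Min–max normalization maps a constant image to all zeros
(a logged, deterministic guard). Resizing is bilinear with half-pixel
centers and edge clamping, clipped to [0,1].

Stochastic augmentation applies only in training mode: a bounded geometric
compose (rotation ±10°, translation ±5%, shear ±5°, horizontal flip 0.5,
reflection padding so borders gain no artificial dark rectangles), a
RandAugment-style policy (N=2 ops at magnitude 9 of 30) over a
grayscale-safe, morphology-preserving pool (rotate, translate, shear,
brightness, contrast, sharpness, autocontrast, equalize, identity — no color
ops), and batch-level MixUp with per-pair λ ~ Beta(0.3, 0.3) shared between
image and label, pairing by random within-batch permutation, applied after
per-image augmentation. Evaluation and test images receive none of this.

## Training

AdamW (betas 0.9/0.999, weight decay 0.05) with norm gains, biases,
attention temperatures, bias tables and prototypes exempt from decay — the
standard exemption; decaying prototypes would drag them off the class
centroids. Cosine-annealed learning rate with a linear warm-up (default 5%
of steps) and configurable floor. EMA of all weights at decay 0.999, with
both raw and EMA weights checkpointed and evaluable — which of the two is
"the" model is left to the user. Batch size 16, reduced automatically for
smaller datasets. A non-finite loss aborts with a diagnostic. All
randomness (shuffling, augmentation, MixUp) flows from one seed; a repeated
run reproduces the loss trajectory bit-for-bit on the same machine.

Full-scale defaults (lr 1e-4, 80 epochs) mirror the reference configuration;
desk-scale runs in the tests and examples train the tiny preset from scratch
for 150–200 steps at lr 2–3e-2 with no warm-up — a few hundred steps cannot
move a from-scratch network at 1e-4, and the hot schedule is the package's
own choice for these run lengths. The epoch-count ambiguity in the source
material (80 vs a maximum of 100) is resolved in favor of the tabulated 80.

## Evaluation protocol

All partitioning is by patient: stratified 80/20 development/test split and
stratified five-fold assignment inside the development set (scikit-learn's
stratified splitters behind the module surface), stratifying on the
patient-level label — the majority label over a patient's images, ties
resolved to malignant (screening-conservative). Metrics treat malignant as
positive throughout. Zero-division conventions: precision/recall 0 on empty
denominators, MCC 0 when a marginal vanishes, κ 0 when chance agreement is
1. Fold aggregation reports the arithmetic mean and the sample (n−1) SD;
a single fold has SD 0 by convention. Uncertainty: percentile bootstrap
(default 10,000 resampled means, 2.5th/97.5th percentiles), seeded. AUROC
is the tie-aware rank statistic; AUPRC is precision–recall step integration;
both error on single-class inputs rather than returning a convention.

## Synthetic data

The generator produces an elliptical breast region on a dark background,
band-limited Gaussian-filtered noise for fibroglandular texture, and
class-dependent lesions: malignant images get either a bright Gaussian mass
(radius 5–10% of the image side) with 6–12 radial spicule strokes, or a
cluster of 5–15 high-intensity dots; benign images get a low-contrast smooth
blob or nothing. Lesion area is kept within 1–15% of the breast region by
shrinking and redrawing when needed. Cohorts draw 1–3 images per patient
(probabilities 0.6/0.3/0.1, mean 1.5), patient-consistent class, malignant
fraction 0.3 by default, with every image paired with its lesion mask and
everything deterministic under the seed.

What this emulates: patient grouping, class imbalance, bright localized
lesions against textured tissue, and enough signal that a trivial
brightness-threshold baseline reaches 0.8 accuracy. What it does not:
breast density spectra, film digitization artifacts, pectoral muscle,
overlapping structures, BI-RADS ambiguity, or realistic lesion morphology.
Passing tests therefore establish that the architecture, optimization and
protocol are implemented correctly and can learn localized-contrast
classification end-to-end — not that the model reaches any particular
accuracy on clinical mammograms.

## Problem sizes in the tests

Unit and property tests run on toy tensors. End-to-end checks use the tiny
preset: an overfit run (32 images, 200 steps, full training accuracy), an
ablation comparison (full model vs passive fusion, 40-patient cohort, 150
steps, 3 seeds), and a held-out generalization run (40 patients, 80/20
patient split). The acceptance script repeats these at the same sizes.
These sizes were chosen as the smallest at which the behaviors of interest
(overfitting, ordering between variants) are stable across seeds.

## Saliency at desk scale: the "echo" effect

A finding worth recording: desk-scale trainings of this architecture on the
synthetic cohorts do not produce lesion-localized Grad-CAM maps, and the
maps are right not to localize. Two regimes were observed. Overfit models
(a few hundred steps on a few dozen images) memorize per-image texture
fingerprints, so their evidence is wherever the texture is. Generalizing
models (held-out AUROC 0.8–0.85) encode malignancy in small *distributed*
shifts of background tokens — the bright lesion changes every token's
normalization context and every attention mixture, and with mean-pooling
over ~144 tokens this "echo" carries more of the pooled signal than the
handful of lesion tokens themselves. Occlusion tests confirm it: deleting
the lesion from the pixels barely moves the posterior of a trained
desk-scale model. The saliency machinery itself is verified exactly
(closed-form linear-GAP oracle, per-operation and end-to-end finite
differences), and `gradcam.lesion_saliency_hit_rate` measures the
localization rate so the property can be tracked; reaching the regime where
lesion-local features dominate requires training scales (and data
realism) beyond a CPU-minutes budget.

## Known limitations

- The autodiff engine is minimal by design: float64, eager, no fusion; a
  base-preset forward pass takes seconds on CPU and full-scale training is
  out of reach — by construction the package targets architectural and
  protocol correctness, not throughput.
- Relative position bias uses a direct table, so weights do not transfer
  across window sizes.
- One prototype per class; multimodal class geometry would need more.
- The passive-fusion ablation shares the post-residual LN structure with the
  cross-guidance path (zeroed-attention equivalence is exact), so it is a
  structural ablation, not a re-tuned baseline.
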