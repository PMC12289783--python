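# Methods

`ddunet` implements a dual-decoder U-Net for binary segmentation of small
lesions in medical-style grayscale images, together with the compound loss
family, paired augmentation pipeline, evaluation metrics, and a synthetic
imbalanced-lesion generator that defines the package's study conditions at
desk (CPU) scale.  This note records the model, its assumptions, the
parameters that matter, and the design choices made where the source
formulation was open or internally inconsistent.

## The problem and the model

Lesions (thyroid nodules, breast masses, liver tumours) typically occupy a
few percent of the pixels of a scan — imbalance regimes of roughly 1:9 for
ultrasound nodules down to 1:50 for liver-CT tumours.  A plain
cross-entropy-trained segmenter minimizes its loss by favouring the
background class and under-segments exactly the pixels that matter.  The
network attacks this from three directions:

**Architecture.**  The encoder has two parallel contraction paths: path one
is the classic 3x3 conv / 1x1 conv (each with batch norm + ReLU) stack with
2x2 max pooling; path two runs at the same cadence and, at each level, adds
in the corresponding path-one features before a further 3x3 conv block.
Three downsamplings with widths (128, 256, 512) and a width-doubling
bottleneck give the canonical 1024-channel 32x32 bottleneck for a 256x256
input.  The per-level combined features form a pyramid refined by a
bidirectional feature pyramid (BiFPN): every merge node computes the
fast-normalized weighted sum

    U = sum_p relu(w_p) / (eps + sum_q relu(w_q)) * I_p,   eps = 1e-4,

with learnable scalar weights, followed by a depthwise-separable 3x3
convolution (batch norm after each convolution) and a Swish activation;
tiers are aligned by a learned 2x deconvolution (upward) and 2x2 max
pooling (downward), and a top-down then bottom-up sweep constitutes one
pass.  After the final pass each tier goes through a feature-optimization
gate — `x * sigmoid(conv1x1(norm(x)))` then dropout — the source lists
these components without the wiring; the multiplicative gate is this
package's realization.

An attention module operates on the coarsest fused tier.  Candidate
embeddings `T_o in R^{A x D}` (A = 2 by default: a background and a
foreground query) first produce a coarse mask `sigmoid(T_o Q^T)` against
the pixel embeddings `Q`; each refinement iteration then updates

    T <- T + softmax((T M_q)(Q M_k)^T + f(a)) (Q M_v),

where `f(a)` adds 0 at positions whose current coarse mask is >= 0.5 and
-1e9 elsewhere, confining attention to predicted foreground.  A candidate
whose coarse mask is entirely empty falls back to unmasked attention
(otherwise its softmax would be a 0/0).  A linear head `L = T M_fc`
classifies each candidate; ties in the argmax resolve to the lowest class
index.  The refined coarse masks are an auxiliary prediction: by default
they do not gate the decoder features (a config flag can multiply the
coarsest tier by the assembled foreground map), but they are supervised by
an auxiliary loss (below) so the module trains jointly with the rest.

Two structurally identical decoders expand the fused tiers back to input
resolution — nearest-neighbour upsampling + 3x3 conv, a pooling-integration
step at each skip junction (3x3 stride-1 average pooling of the upsampled
high-level features, additive fusion with the skip features, 1x1
conv/norm/ReLU), and a 3x3 refinement per level, with a 3x3 + 1x1 head.
One decoder scores foreground (`M_F`), the other background (`M_B`).  The
final probability map is, by default,

    O_Final = (sigmoid(M_F) + 1 - sigmoid(M_B)) / 2,

treating `M_B` as background evidence.  The source prints
`1 - (sigmoid(M_F) + sigmoid(M_B))/2`, which evaluates to exactly 0.5 for
ideal complementary decoders; that form is retained as `fusion_mode =
"verbatim"` for audits, and the degeneracy is asserted in the tests.
Binarization threshold is 0.5 throughout.

**Loss.**  The integrated loss is

    I = alpha * D + beta * C + delta * R + gamma * B

with D the foreground Dice loss `1 - 2 sum(S f) / (sum S + sum f + eps)`,
C the sum of foreground and background Dice losses, R a per-class
soft-recall penalty, and B binary cross-entropy.  The source never prints
the four weights ("adjusted to optimal values"); the defaults are a neutral
0.25 each and fully configurable.  The printed recall formulas carry a
factor of 2 (so perfect recall scores -1) and, in the background term, an
undefined symbol; the default `canonical` mode drops the factor — each term
is one minus soft recall, in [0, 1], with an image containing no foreground
contributing a zero foreground term — while `verbatim` mode evaluates the
printed expressions (reading the undefined symbol as the background
ground-truth indicator) and reproduces the -1 anomaly on demand.  Ratio
denominators carry `eps = 1e-6`; BCE probabilities are clamped at 1e-7.

During training each decoder output and the fused map receive the full
integrated loss (background decoder against the complement mask), combined
with the published weights 0.6 (background) and 0.2 (foreground); since
those sum to 0.8 and the text says the final merger also contributes, the
remaining 0.2 weights the fused-output loss (configurable; setting it to 0
recovers the published two-term form).  An auxiliary term (weight 0.1)
supervises the attention module: each candidate's coarse mask gets a BCE
against the block-downsampled ground truth (complement for the background
candidate) and the candidate logits a cross-entropy against their
designated labels.  This both regularizes the coarse masks and guarantees
every parameter group receives gradient, which the tests assert.

**Data.**  Augmentation follows the stated recipe: rotation in [-10, 10]
degrees, scaling 90–110%, random translation, horizontal/vertical flips.
The translation magnitude is unstated in the source; the default is ±10% of
the image side, matching the spirit of the other ranges.  Per-transform
application probability (also unstated) defaults to 0.5.  The affine part
is applied in the fixed order rotate -> scale -> translate (composed into a
single warp to avoid repeated resampling), then flips; images are resampled
bilinearly, masks with nearest neighbour and re-thresholded at 0.5;
out-of-canvas pixels are 0.  Resizing targets 256x256 at full scale (the
desk-scale defaults use 64), intensities are divided by 255, denoising is a
Gaussian blur, and contrast enhancement is classic 8-bit CDF histogram
equalization (a constant image is returned unchanged).

## Synthetic data: what it emulates and what it does not

The generator stands in for the ultrasound/CT corpora: each image is a
smooth textured background (low-frequency Gaussian field around intensity
0.4) carrying 1–3 bright blobs — randomly oriented ellipses whose radius is
perturbed by low-order angular harmonics (amplitude <= 0.12 on harmonics 2
and 3) — brightened by `lesion_contrast` (default 0.35) after a sigma-1
smoothing of the mask, plus pixelwise Gaussian noise (sd 0.05).  The
foreground fraction of every mask is driven into the configured interval by
iteratively rescaling blob radii (`sqrt(target/actual)`, up to 15 rounds),
so fraction control is exact up to rasterization quantization.  Presets
encode the reported imbalance regimes: (0.08, 0.12) for the ~1:9
ultrasound datasets and (0.015, 0.025) for the ~1:50 liver-CT regime.

It does **not** emulate speckle statistics, attenuation shadows, Hounsfield
calibration, anatomy, or annotation noise.  Passing tests therefore show
that the architecture, losses and training loop behave as specified and
that the compound loss recovers minority-class pixels on controlled
imbalanced data — not that the published benchmark numbers transfer.

## Numerical and engineering choices

The network runs on a small reverse-mode autodiff engine over NumPy arrays
written for this package (convolutions via strided patch views + einsum,
hand-derived adjoints; a pointwise-conv GEMM fast path).  Working precision
is float64 by default — the loss/metric exactness tests assert at 1e-9 and
1e-12 — with a float32 context used for training runs, which roughly
triples throughput on CPU.  Weight initialization is He-normal for
convolutions and Xavier-uniform for attention projections, drawn from a
generator seeded by the model config, so models, training runs and datasets
are bit-reproducible from their seeds.  SGD uses the published recipe
(lr 0.01, momentum 0.9, weight decay 1e-4, batch 16).  Early stopping
monitors validation loss with patience 20 (unstated in the source) and
restores the best weights; validation can be evaluated every k-th epoch
(`eval_every`) to save time, in which case patience counts evaluation
passes.  Metrics are macro-averaged (mean of per-image values); a metric
with an empty denominator is 1 when prediction and truth agree perfectly
and 0 otherwise, and the event is logged.  The printed IoU and DSC formulas
are interchanged relative to their standard definitions; the standard set
is the default and the printed set sits behind `formula_set="verbatim"`.

Deviations and interpretations worth noting:

* Decoder upsampling uses nearest-neighbour + 3x3 convolution (the learned
  deconvolution appears where the source names it, i.e. BiFPN tier
  alignment).  Bilinear + conv was considered; at these widths the choice
  is immaterial to any tested property and nearest keeps the resampling
  adjoint trivial.
* The source's tier arithmetic ("F_3 at 64x64 = 256/2^3" but also "F_6 at
  8x8 = 256/2^6", tiers "2 to 7" vs "F_1..F_7") is internally inconsistent;
  tiers here are the encoder levels 0..n_downsamples with spatial size
  input/2^i, i.e. four tiers for the default three downsamplings.
* Eq-level subscript swaps in the printed Dice pair (foreground labelled
  with subscript 0) are resolved by a fixed convention: subscript 1 =
  foreground everywhere in this package.
* The source states both an 80/10/10 split and five-fold cross-validation;
  both are provided (`split_dataset`, `kfold_split`).
* A mention of RandAugment appears only in the source's conclusion and
  contradicts its own fixed augmentation list; the fixed list is what is
  implemented.

## Problem sizes

The bundled experiments are sized for a single CPU: the reduced-width
configuration (`ModelConfig.tiny`: widths 4/8/16, 8-channel BiFPN, 16-dim
attention) is used for the overfit check (one 64x64 pair, 500 SGD steps,
integrated loss on the fused output < 0.05) and for the imbalance
comparison (60 images at 64x64 with ~5% foreground, 20 epochs, 3 seeds per
loss mode; held-out per-image foreground recalls pooled over seeds and
summarized by their median).  The full-width 256x256 configuration is
constructed and shape-checked but not trained in the test suite.
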