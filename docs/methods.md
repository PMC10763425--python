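# Methods

This note documents the models, the synthetic data generator, the numerical
choices and the known limitations of `pneumonet`.

## Problem setting

Binary classification of frontal chest radiographs into pneumonia (label 1,
the positive and majority class) and normal (label 0). The class imbalance
ratio of the emulated collection is 4,273:1,583 ≈ 2.70. Evaluation follows
the standard confusion-matrix metrics with pneumonia as the positive class;
sensitivity is reported as an alias of recall because the two are the same
formula, TP/(TP+FN).

## Architectures

**Side-branch attention net.** The input (H, W, c) is lifted to
`stem_channels` by a 3×3 convolution (batch norm + ReLU), then passes
through `n_blocks` shape-preserving blocks. Each block computes

    out = F + fuse( MainConv(F), Σ_{b=1,2} Up_b(ReLU(BN(Reduce_b(F)))) )

where `Reduce_b` is a 3×3 convolution with stride `s` mapping C → C/r
channels, `Up_b` is a 2s×2s transposed convolution with stride `s` restoring
H×W×C exactly, and `MainConv` is a 3×3 same convolution. `fuse` is
element-wise addition by default; in gated mode the branch sum instead passes
through a sigmoid and multiplies the main path. Every convolution is
followed by batch normalization; the branch bottleneck carries the ReLU
nonlinearity, and each block is wrapped in a residual skip so a zero-branch
block is the identity. A global average pool and a linear layer produce two
logits. At the full-scale configuration (512×512×3 input, 64 channels,
8 blocks) the feature map stays 512×512×64 through all blocks; the desk
configuration (64×64×1, 8 channels, 2 blocks) keeps the same topology at CPU
scale.

Side-branch kernel geometry (3×3 stride-2 reduce with r = 4, 4×4 stride-2
transposed-conv upsample) is a standard encoder–decoder pairing chosen so
the upsample restores the input size exactly for any even H, W; the
constraint is `up_ksize − 2·pad = stride`.

**Channel attention** (off by default, available for ablation): gates
`σ(W₂ ReLU(W₁ d))` on the pooled channel descriptor `d = GAP(F)` rescale
channels; gates lie strictly in (0, 1).

**Residual baseline.** A depth-reduced ResNet-style classifier: 7×7/2 stem
with max pooling, then basic two-conv residual stages that halve resolution
and double channels, global average pooling and a linear head.
`resnet_shape_walk` reports the canonical full-depth dimension walk
(224 → 112×112×64 → 56×56×64 → 56×56×256 → 28×28×512 → 14×14×1024 →
7×7×2048) as pure shape arithmetic.

## Losses

All losses operate on the predicted probability of class 1,
`y' = softmax(z)₁`, clamped to [ε, 1−ε] with ε = 1e-7 before logarithms
(natural log throughout). Defaults α = 0.25, γ = 2 — the canonical focal
settings.

- cross-entropy: `−[y ln y' + (1−y) ln(1−y')]`
- focal: `−α_t (1−p_t)^γ ln p_t` with `p_t = y'` if y = 1 else `1−y'`
- modified focal: the focal branches additionally scaled by `1/√n`:
  `w₁ = α/√n_a` for y = 1 and `w₀ = (1−α)/√n_b` for y = 0.

The count pairing (`n_a`, `n_b`) has two modes. `as_printed` pairs the y = 1
branch with the *normal* count and y = 0 with the *pneumonia* count,
reproducing the source formula verbatim; under the label convention
1 = pneumonia this up-weights the majority branch. `per_class` (the training
default) pairs each branch with its own class count, which matches the
stated intent of up-weighting minority classes. Both are kept because the
formula's label convention is ambiguous; the switch is one config key. At
symmetric predictions the per-sample ratio between the two branches is
`√(n_major/n_minor)·α/(1−α)` in `as_printed` mode, which the tests verify to
1e-10.

Gradients with respect to `y'` are analytic and checked against central
finite differences (1e-6) on a probability grid; training backpropagates
them through the softmax.

## Training recipe

AdamW (decoupled weight decay; the recipe's "momentum" 0.9 is read as the
first-moment coefficient β₁, with β₂ at the conventional 0.999), step
schedule `lr(e) = lr₀ · γ_lr^⌊e/step⌋`, fixed epoch budget, no early
stopping, no augmentation, full-validation accuracy at every epoch end.
Defaults are the full-scale recipe: batch 16, lr₀ = 5e-5, weight decay 1e-4,
×0.1 every 5 epochs, 100 epochs.

The desk preset (`DESK_TRAIN_CONFIG`) keeps batch 16 and the ×0.1/5-epoch
schedule but uses lr₀ = 3e-3 and 6 epochs: a from-scratch run of a few
hundred 64×64 images cannot move its weights appreciably in a handful of
epochs at 5e-5, while at 3e-3 the separable phantom task converges by epoch
2–3. These values were fixed once as the package's CPU-scale study
conditions. All randomness (initialization, batch order, data generation)
derives from explicit seeds; (config, seed) → history is bit-reproducible on
one machine.

The ablation runner trains three variants on byte-identical per-seed
datasets — (a) residual baseline + cross-entropy, (b) side-branch attention
net + cross-entropy, (c) side-branch attention net + modified focal loss —
over five seeds and reports per-variant mean/sd/median of all metrics,
including minority-class recall (the normal class, i.e. specificity under
the label convention).

## Synthetic radiograph phantoms

`synthetic_xray` emulates the statistical shape of an imbalanced pediatric
chest X-ray collection, not its anatomy. A phantom is a bright body ellipse
(intensity 0.85) on a mid-gray background (0.50) with two darker
axis-aligned elliptical lung fields (0.25) and periodic rib bands; additive
Gaussian noise (default sd 0.05) is clipped to [0, 1]. Positive samples add,
strictly inside the lung masks and strictly non-negatively: Gaussian-blurred
bright blobs (infiltrates), small disjoint bright discs (nodules), an
optional lower-lobe consolidation, a global density lift (0.15 ×
`density_shift`), and an optional bright pleural band obtained by mask
erosion. Defaults per positive image: 2 infiltrates, 3 nodules,
consolidation probability 0.5, density shift 0.3, pleural band probability
0.3.

Two presets: the full-count spec (4,273/1,583) for bookkeeping, and the desk
spec (64×64, 270/100 — the same ≈2.70 ratio — noise sd 0.05) for training
studies. Lung masks are fixed ellipses so inside/outside contracts are
testable by direct pixel statistics; with zero noise the total added
lung-field brightness separates the classes perfectly, which is what makes
the desk-scale learnability checks meaningful.

What passing tests on phantoms do **not** show: robustness to anatomical
variation, projection geometry, exposure differences, or subtle textural
disease signs of real radiographs. The generator guarantees the pipeline is
correct and the optimization behaves as designed; it says nothing about
clinical performance, and the headline accuracies of the original clinical
study are deliberately not reproduction targets here.

## Numerical choices and conventions

- Engine: NCHW float32 tensors (float64 available for oracle tests);
  convolution via im2col + GEMM; the transposed convolution and the
  convolution input-gradient share one code path (zero-dilation + flipped
  kernel), verified against scipy correlation and loop-based oracles to
  1e-10 and against numerical gradients to 1e-8.
- Batch norm: ε = 1e-5, running-stat momentum 0.1; biases and norm
  parameters are excluded from weight decay.
- He-normal initialization from a per-build `numpy` Generator, so equal
  seeds give identical parameters.
- Metrics use exact `Fraction` arithmetic on integer counts; a zero
  denominator yields `None` (with a logged warning) rather than 0 or an
  exception, so ablation tables never silently corrupt.
- Image I/O: per-image min–max rescale to [0, 1], bilinear resize, 8-bit
  PNG output; unreadable files are skipped with a warning, an empty class is
  an error.
- Splits are drawn per class from a seeded permutation; requests exceeding
  availability raise an error naming the class.
- Nodule placement uses rejection sampling with a pairwise centre-distance
  margin > √2 beyond the radii sum, guaranteeing disjoint connected
  components after lung-mask clipping.

## Known limitations

- The phantom generator is deliberately simple (fixed elliptical masks,
  additive lesions); it cannot emulate contrast/resolution/noise quality
  indices of a real collection, and no such indices are computed.
- Full-scale (512×512, 8-block, 100-epoch) training is supported by the
  code but not exercised in tests; all empirical claims are desk-scale.
- The CNN engine targets clarity and reproducibility over speed: roughly
  6 s/epoch for the desk attention net on one CPU core.
- Only binary classification; no viral/bacterial subtyping, no ROC/AUC, no
  pretrained weights or transfer learning.
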