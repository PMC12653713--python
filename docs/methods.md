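# Methods

This note documents the models, formulas, numerical choices and known
limitations of the package. Everything stated here is computed by the code;
nothing is quoted from measurements the package cannot reproduce.

## Problem setting

Tongue inspection in traditional Chinese medicine reads diagnostic
information from tongue color, so automated tongue analysis needs captured
images whose colors are faithful to the scene. Varying illumination
introduces *color casts* — global shifts of all pixel colors. The package
simulates such casts on paired data, corrects them with classical
white-balance algorithms or a trained convolutional regression network,
and quantifies the residual error.

## Cast simulation

Five canonical degradations act on 8-bit RGB values `v`:

* lower / higher brightness: `v → v·contrast ∓ offset`, with
  `contrast ∈ [0.8, 1]` and `offset ∈ [0, 30]` levels. The affine result
  is computed in floating point and not clipped anywhere in the math; a
  single round-half-away-from-zero quantization with clamping to [0, 255]
  happens at the 8-bit boundary (with these ranges the raised value can
  reach at most 285 pre-clamp).
* reddish / greenish / bluish: `v → min(255, v + adjustment)` on the one
  affected channel, canonical `adjustment = 50` levels.

Randomized-severity specs draw contrast and offset uniformly from the
ranges above; the cast adjustment is drawn uniformly from the integers
10–50, spanning mild casts up to the canonical severity. The sampling law
for random severities is this package's choice (documented, seeded,
replayable); integer adjustments keep channel-cast arithmetic exact in
8 bits.

## Evaluation metrics

For a (reference, test) pair the report contains:

* **ΔE (CIE76)** — per-pixel Euclidean distance in CIELAB, summarized as
  mean, Q1, Q2, Q3 (linear-interpolation quantiles over all pixels of the
  pair) and maximum. Conversion uses the standard sRGB companding → XYZ
  (D65) → Lab route; the source text names no illuminant, and D65/sRGB is
  the reproducible convention. CIEDE94/2000 variants are deliberately out
  of scope. Cast grading from mean ΔE: `< 6` same, `[6, 15)` mild cast,
  `≥ 15` cast. The published criteria leave exactly 15 unassigned
  (`< 15` mild, `> 15` cast); the boundary is graded as a cast here —
  conservative flagging.
* **MAE, RMSE** — on pixel values normalized to [0, 1].
* **PSNR** — `20·log10(255 / RMSE₂₅₅)` on the 0–255 scale with
  `MAX_I = 255`; identical images report `inf` rather than raising.
  The two scales coexist on purpose and are both stated in the API docs.
* **SSIM** — per channel with an 11-tap Gaussian window (σ = 1.5),
  constants `c1 = (0.01·255)²`, `c2 = (0.03·255)²` (the originating SSIM
  convention), averaged over channels. Computed via scikit-image.

## Classical correctors

* **Gray world**: scale each channel by `K/mean`, `K` the mean of channel
  means. Post-condition: absent clamping, corrected channel means agree
  within 0.5 level.
* **Perfect reflection**: the pixel maximizing R+G+B is assumed white;
  channels scale by `255/component`. Ties break to the first pixel in
  row-major order (determinism). The scaling multiplies before dividing
  (`v·255/c_max`) so exact half-integers round predictably.
* **SDW**: gray world on block-weighted means over 16×16 blocks; the
  weight of a block is its spatial standard deviation (per-channel std
  over pixels, averaged across channels), normalized to sum to one. Flat
  single-color swaths thus contribute ≈ nothing to the illuminant
  estimate. The weighting formula is not printed in the source
  description, which is qualitative; this is the simplest reading of
  "weights based on the standard bias" and is a documented assumption.
  All-blocks-flat degenerates to plain gray world.
* **Polynomial chart calibration**: least squares from a monomial
  expansion of observed 24-patch chart colors to reference colors. The
  default expansion is the standard second-order 11-term set
  {R, G, B, R², G², B², RG, RB, GB, RGB, 1}; the three linear terms are
  required so the identity lies in the model class. Fitting happens on
  [0, 1]-scaled colors for conditioning. The printed matrix equation for
  this method is ambiguous about which factor holds the expanded observed
  colors; the standard least-squares orientation
  (expanded-observed → reference) is used. The embedded chart is the
  widely published nominal sRGB ColorChecker Classic list; users can
  override it from CSV.

All correctors compute in float and quantize once at the output.

## TococoNet

A fully convolutional image-to-image regressor:

```
x → U-Block₁ → concat(·, x) → M-Block → concat(·, previous) → U-Block₂
  → BatchNorm → 1×1 conv (64) → ReLU → 3×3 conv (3, linear)
```

* **U-Block** (in, mid = 32, out = 64): two-level symmetric
  encoder–decoder — per level two 3×3 convs; 2×2 max-pool down, ×2
  bilinear up (half-pixel-center convention); concatenation skips join
  matching levels; an additive residual connects block input to block
  output. Deepest features sit at 1/4 resolution; two upsampling passes
  restore the input size, so block inputs must have spatial dims divisible
  by 4 (whole-image inference reflect-pads and crops).
* **M-Block** (filters = 32, out = 64): 8 stacked 3×3 convs at constant
  resolution; the stack's features are concatenated with the block input
  before the 8th conv, which acts as the fusion projection back to 64
  channels. (The published block description contains one sentence that
  attributes pooling and rescaling to this block, contradicting its own
  constant-scale statement; only the unambiguous properties — 8 convs at
  constant resolution — are implemented.)
* **Head**: BatchNorm → 1×1 conv (64) → 3×3 conv (3), the final conv
  linear (regression head). ReLU follows every other conv; the activation
  choice is not printed and ReLU is the standard default.

Conv-layer budget: 8 + 8 + 8 + 1 + 1 = **26**, verified structurally by
`audit_architecture` at construction. Because the budget is exact, the
residual shortcut must not add a projection conv: when block input and
output channel counts differ, the shortcut zero-pads (or truncates to) the
output width — a parameter-free identity in the style of ResNet's option-A
shortcut. For the second U-Block, whose input is the concatenation
[M-Block output ‖ earlier features], truncation passes exactly the M-Block
output through the shortcut. The precise tensors carried by the
inter-block concatenations are likewise not printed; the wiring above
(each block's output concatenated with its own input) is a documented
assumption satisfying "fusion of features at different levels".

**DCCN baseline**: 5 convs (6→32→32→32→32→3), no pooling, no batch norm;
the three color-adjustment scalars are broadcast to constant feature
planes appended to the RGB input. Per-layer filter counts are unprinted;
32 is a documented default.

### Numerics engine

No deep-learning framework is part of the dependency set; the networks run
on a compact numpy engine written for exactly this layer vocabulary:
im2col + GEMM convolution in NHWC layout, argmax-tracked 2×2 max pooling
(ties to the first occurrence), matrix-form separable bilinear upsampling,
batch normalization with running statistics (momentum 0.1, ε = 1e−5), Adam
(β = 0.9/0.999, ε = 1e−8, classic L2 weight decay added to the gradient),
and a reduce-on-plateau scheduler. Backward passes are hand-derived and
verified against central finite differences in float64 (relative error
≲ 1e−6) in the test suite. Default precision is float32; tensors range
over [0, 1] inside the network, with quantization only at the image
boundary. Forward passes are bit-deterministic for a fixed seed and input
on one machine.

## Training protocol

Full-scale defaults follow the published setup: MSE loss, Adam, batch 32,
200 epochs, learning rate 1e−4, L2 weight decay 1e−5, and halving of the
learning rate after 15 epochs without validation improvement ("no
improvement" means less than 1e−6 absolute decrease — the patience is
published, the tolerance is ours). The lowest-validation-loss parameters
are retained. Training PSNR is computed on [0, 1] tensors and reported on
the 255 convention.

Patches are 160×160 crops at step 80 (49 per 640×640 image). The split is
60/30/10 **by source image**, not by patch: overlapping patches of one
image are near-duplicates, and patch-level splitting would leak them
across splits. This is a deliberate deviation from a protocol that does
not state its split unit, in favor of honest generalization measurement;
the `PatchDataset` container enforces leak-freedom as an invariant.

## Synthetic scenes

Each scene is an anti-aliased reddish ellipse (base color jittered around
(180, 90, 95)) with a radial lightness gradient (default amplitude 25
levels), Gaussian speckle (σ = 6 levels), an optional pale coating patch
(probability 0.3), on a neutral background (205, 205, 200), 640×640 by
default. Block fixtures draw uniform patches from a truncated Gaussian
around (180, 90, 95) (σ = 40) with a 15% admixture of neutral grays, which
exercises both the saturating and non-saturating paths of the channel-cast
formula. Realism is deliberately minimal: cast correction depends on color
statistics, not anatomy. What passing tests on these fixtures do **not**
show: robustness to real tongue texture, specular highlights, shadows,
mixed or spatially varying illumination, or camera processing pipelines.

## Desk-scale learning experiment

`tococonet.experiments.scaled_down_recovery` is the package's end-to-end
check that the architecture learns cast removal, at CPU scale: a reduced
TococoNet (mid 8 / out 16 filters, same topology, same 26-conv budget)
trained on 304 bluish-cast (adjustment 50) 64×64 pairs from 32 rendered
256×256 scenes, split 60/30/10 by image. Optimization uses batch 8 and
learning rate 3e−3 — more steps per epoch and a faster rate than the
full-scale defaults, appropriate for the small model and short budget —
for at most 20 epochs, stopping early when validation MSE falls below
1.5e−3 (≈0.04 RMS on [0, 1], well past cast removal). Success criterion:
held-out mean ΔE reduced by at least 50% relative to the biased input.
The problem sizes are chosen so the experiment completes in minutes on a
single CPU core.

## Statistical comparison

Per-image metric lists are summarized by 40 bootstrap resamples with
replacement at full list size (mean and sample sd of resample means), and
methods are compared with classical two-sided paired t-tests
(t = mean(d)/(sd(d)/√n), n−1 df) at α = 0.001. Identical vectors are the
defined degenerate case t = 0, p = 1; a nonzero constant difference gives
t = ±∞, p = 0. No multiple-testing correction is applied across the five
scenarios × two metrics, matching the protocol being followed; outputs say
the p-values are raw.

## Known limitations

* The engine is CPU-only and orders of magnitude slower than a GPU
  framework; full-scale (32-filter, 160×160, 200-epoch) training is out of
  desk reach, so published full-scale results are not reproduced here —
  only structural properties and scaled-down learning behavior are tested.
* Casts are global and single-axis; mixed or spatially varying casts and
  physically based illuminant spectra are non-goals.
* The synthetic scenes carry no anatomy; conclusions about real tongue
  photographs require real data.
* SSIM is undefined for images smaller than the 11-tap window.
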