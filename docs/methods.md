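# Methods

## Problem setting

Blurred brightfield (or fluorescence) frames from long-term live-cell
imaging are enhanced by a conditional GAN trained on paired
(degraded, sharp) images of the same field of view. Real pairs of this kind
come from defocus Z-stacks (an out-of-focus layer paired with the focal
layer) or from synthetically blurring sharp frames; this package generates
both kinds synthetically, since no public dataset accompanies the task.

## Model

**Generator.** Conv stem → `n_down` stride-2 convolutions (leaky-ReLU) into
a latent representation → `n_residual` residual blocks → mirrored
transposed-convolution upsampling → 1×1 conv head. The head predicts a
*logit residual*: the output is `sigmoid(head(x) + logit(input))`, so an
untrained generator is the identity map and training only has to learn the
sharpening correction. This single global shortcut is standard practice in
super-resolution generators; the decoder deliberately has no per-scale
(U-net-style) skip connections, which are left out of scope. No published
reference layer counts exist for this task, so the architecture is a
faithful-genre stand-in; widths and depths are configurable
(`GeneratorConfig`), with defaults small enough to train on one CPU.

**Discriminator.** Stride-2 leaky-ReLU convolutions, a 1-channel conv head,
global average, sigmoid → one probability per image. Both networks are
all-convolutional (no fully connected layers), which tests assert by
inspecting parameter shapes.

**Backend.** No deep-learning framework is used: `cellsharp.nn` implements
Conv2d (im2col + matmul), its exact adjoint ConvTranspose2d, pointwise
nonlinearities, residual blocks and Adam, with manual backpropagation.
All layer gradients are finite-difference-checked in the test suite.
Forward/backward run in float32; losses are reduced in float64.

## Objective

- Discriminator: `L_D = −mean[log D(x) + log(1 − D(x̂))]`.
- Generator: `L_G = λ_rec L_rec + λ_feat L_feat + λ_style L_style +
  λ_tv L_tv + λ_adv L_advG` with the *non-saturating* adversarial term
  `L_advG = −mean[log D(x̂)]`. The printed minimisation of `log D(x̂)`
  would reward a *failing* generator; the non-saturating form shares its
  optimum with the theoretical objective and keeps early gradients alive,
  and the sign convention is documented here once.
- `L_rec` is the mean squared pixel error over `B·C·H·W`.
- `L_feat` sums `‖Φ_i(x) − Φ_i(x̂)‖²/(B·C_i·H_i·W_i)` over the taps of a
  frozen feature extractor. The canonical extractor in this literature is
  an ImageNet-pretrained VGG-16/19; downloading pretrained weights is not
  assumed here, so the default is a **frozen random convolutional
  extractor** (seeded, 3 taps, widths 8/16/16, strides 1/2/2) with the same
  tap structure. Random deep features are an established usable perceptual
  basis; the extractor's provenance travels in its `descriptor` string and
  any extractor with the same interface can be plugged in.
- `L_style` uses per-item Gram matrices `A·Aᵀ` of the channel-unfolded
  taps, squared Frobenius distance, normalised by the feature element count
  exactly as the objective is printed. A `normalize_gram` flag provides the
  conventional additional `1/(C·H·W)` Gram scaling.
- `L_tv` penalises squared adjacent-pixel differences, rows and columns
  separately, normalised by `B·C·H·W`.
- Discriminator outputs are clamped to `[1e−7, 1 − 1e−7]` before any log.

**λ defaults** (`LossWeights`): `λ_rec = 1`, `λ_feat = 0.05`,
`λ_style = 1e−4`, `λ_tv = 1e−4`, `λ_adv = 1e−3`. There are no canonical
values for these weights; these were calibrated on the synthetic benchmark by measuring
term *gradient* scales (not just values): with the unnormalised Gram the
style gradient is ~10³× the pixel-loss gradient on fixture pairs, and any
larger `λ_style` visibly stalls supervised learning — the generator stays
pinned at identity. At these defaults the pixel term dominates and each
perceptual term contributes at the few-percent gradient level.

## Training schedule

Three phases (generator warm-up on the non-adversarial terms; discriminator
warm-up against frozen-generator fakes; the full alternating game), default
1000/1000/10000 steps for full runs and 300/300/1500 in the scaled-down
benchmark. Optimizer: Adam, lr 2e−4, betas (0.5, 0.999) — DCGAN-standard,
configurable. One D step per G step in phase 3 (configurable). Batch-size
regimes follow (input px → batch): 128→32, 256→20, 512→4, with 256/20 the
canonical full-scale default; the toy benchmark uses 64 px / batch 4.
Batch sampling is the only randomness and flows from the config seed;
checkpoints store weights, Adam state, step and sampler RNG state, so
`resume(train(n)) ≡ train(2n)` bit-exactly. A non-finite loss aborts with
the offending term named.

## Synthetic data

`SceneSpec` scenes emulate what matters for this task: a mid-grey (~0.40)
background with an oriented illumination ramp, soft-edged elliptical cells
only mildly brighter than background (brightfield contrast is low —
which is also why CLAHE genuinely widens the histogram of these images),
spatial clustering, smoothed intra-cell texture, and small dark dead-cell
disks (2–5 px). Degradation order is blur → contrast/brightness scaling
about the mean → additive Gaussian noise → clamp, mimicking
optics-then-sensor physics. Z-stacks map defocus to blur as
`σ_px = 0.15 · |Δz| µm / pixel_size` (0.65 µm/px default), which makes the
1.5–18 µm interval regimes visibly distinct; the focal layer of an
even-length stack is the lower middle.

What the generator does **not** model: physically rigorous PSF shapes,
fluorescence photophysics/photobleaching, multi-layer occlusion, real
camera noise statistics. Passing benchmarks on these scenes therefore
demonstrates that the pipeline mechanics work (training improves fidelity
and bandwidth on held-out data), not performance on real micrographs.

## Classic baseline

TE = unsharp masking then CLAHE; sharpness first, contrast second.
Defaults: radius 2 px, amount 1.0, clip limit 0.01 (normalised), 8×8 tiles
— common-practice values; they are
fixture-tested, not claimed to reproduce anyone's numbers. EGT (enhanced
ground truth) is this pipeline applied to the sharp target; training with
EGT targets is the "plus" variant and needs no special trainer.

## Metrics

- PSNR on the [0,1] scale (peak 1 ≡ 255 at 8 bit); identity pairs report a
  100 dB cap instead of +∞. NRMSE normalises RMSE by the reference range.
- MS-SSIM per the standard 5-scale exponents (0.0448, 0.2856, 0.3001,
  0.2363, 0.1333), Gaussian window σ = 1.5; coarse scales contribute
  contrast-structure, the finest retained scale the full SSIM; images too
  small for 5 scales reduce the pyramid with a warning and renormalised
  exponents. Checked against an independent scalar-loop implementation.
- Entropy and mutual information in **bits** (log base 2 — the base is a
  convention choice) on the 8-bit requantised scale with 256 bins,
  matching how grey-level archives are stored. `I(a,a) = H(a)` exactly
  under shared binning.
- **Decorrelation resolution**: the mean-subtracted image is edge-apodised
  (Tukey window, α = 0.25, to suppress boundary ringing), Fourier
  transformed; the decorrelation function
  `d(r) = Σ_{|k|≤r} |I(k)| / sqrt(Σ|I|² · #{|k|≤r})` — the masked
  cross-correlation between the spectrum and its phase-normalised version —
  is evaluated on 50 radii for the raw spectrum and 10 geometrically spaced
  Gaussian high-pass strengths. `k_c` is the highest local-maximum
  frequency over all curves (peak prominence 1e−3); with no local maximum
  anywhere, the global maximum of the unfiltered curve is used and flagged.
  `resolution = 2·pixel_size/k_c`; the estimate is invariant to global
  intensity scaling, and requires min side ≥ 64 px.

## Tiled inference

Default 256 px tiles with 32 px overlap. Feather blending uses separable
linear ramps with per-pixel weight normalisation; it is identity-preserving
to ~1e−15 (floating-point rounding of the weight normalisation).
Center-crop mosaic assigns each pixel to exactly one tile and is
bit-exact for an identity generator; with a translation-equivariant
generator its interior matches whole-image inference to ~1e−5 (float32
boundary effects only). Undersized inputs are reflect-padded to one tile
and cropped back.

## Scaled-down benchmark

`toy_deblur_benchmark`: 220 paired 64 px scenes at blur σ = 2 px
(200 train / 20 held out), 300/300/1500 steps, generator base width 16 with
2 downs and 3 residual blocks, discriminator base 8. Problem sizes were
chosen so the full run takes a few minutes single-threaded (batch 4,
~5 min). The trained generator must beat the blurred inputs on held-out
PSNR (threshold +2 dB; observed gains are +5.7 to +5.9 dB across seeds)
and on decorrelation resolution (observed ~4.2 µm → ~1.5 µm, i.e., close
to the ~1.5 µm the sharp targets themselves measure).

## Known limitations

- The architecture is a pragmatic CPU-scale design, not a replica of any
  particular published network, and no public hiPSC-CM image set exists to
  score it against; quantitative results apply to the synthetic scenes only.
- The random-feature extractor is weaker than a pretrained VGG; perceptual
  terms act mainly as regularisers at toy scale.
- The identity-example edge case: a freshly initialised generator is
  already (near-)identity by construction, so "learns identity" sanity
  checks assert that training keeps the pixel loss far below the image
  variance scale rather than a relative drop from an already-tiny start.
- CZI containers, OME metadata, instrument-side mosaic stitching,
  Wasserstein/hinge objectives and learned perceptual metrics are out of
  scope.
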