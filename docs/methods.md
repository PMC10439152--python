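# Methods

## Model

The framework is a conditional adversarial segmenter.  A generator G maps an
RGB dermoscopy image x ∈ [0,1]^{H×W×3} to a lesion probability map
ŷ ∈ (0,1)^{H×W} (sigmoid head).  A patch discriminator D maps a single-channel
mask or probability map to an m×n grid of patch scores in (0,1).  Training
alternates one discriminator update (binary cross-entropy: ground-truth masks
toward 1, detached generator output toward 0) with one generator update on

L = L_dice + w_s · L_smooth + λ_adv · BCE(D(G(x)), 1),

the non-saturating generator objective: instead of maximizing the
discriminator's error on fake labels, G minimizes the cross-entropy of its
output being scored *real*, which has stronger early-training gradients and
the same fixed point.  The conceptual min–max objective is the classical
two-player value function; the non-saturating form is the practical variant
used by essentially all patchGAN-style training.

The discriminator sees the mask/probability map alone (one channel), not an
image–mask pair: its role is to judge whether a mask is shaped like a human
annotation, independent of the photograph.

### Dice loss

`1 − 2Σŷy / (Σŷ² + Σy² + ε)`, summed over all pixels of one image; for a
batch, per-image losses are averaged.  ε = 1e−7 guards the all-empty case.
Its value lies in [0,1] since 2ab ≤ a² + b².

### Boundary-smoothing loss

An ordered-pair sum over the 4-neighbour system: for every pixel i and each
in-grid 4-neighbour j, the term B(i,j)·y_i·|ŷ_i − ŷ_j| accumulates, with
B(i,j) = 1 iff the ground-truth labels of i and j agree.  Out-of-grid
neighbours are skipped, so interior/edge/corner pixels contribute 4/3/2
ordered pairs.  Because the double sum enumerates ordered pairs, each
unordered same-label pair contributes twice — this is the tested reference
convention; an unordered enumeration would halve every value.  The y_i factor
means smoothness is enforced only where the ground truth is foreground; the
implementation follows that definition exactly rather than symmetrizing it.
The raw sum is the reference contract; for training, a per-pixel-mean
normalization (`normalize=True`, default in the trainer) keeps the term on
the same scale as the dice loss, with weight w_s = 1.

The |·| term has a kink at ŷ_i = ŷ_j; the backward pass uses the sign
subgradient (0 at ties), which is standard for L1-type penalties.

### Adversarial loss

Mean binary cross-entropy over patch scores, with scores clamped to
[ε, 1−ε], ε = 1e−7.  The real + fake sum is bounded below by 2·log 2,
attained when every score is 0.5 — the indifferent-discriminator fixed
point, used as a sanity anchor in tests.

## Architectures

### Patch discriminator

Five convolutions, kernel 4, stride 2, padding 1, widths 64-128-256-512-1,
LeakyReLU(0.2) after layers 1–4, sigmoid after layer 5, no batch
normalization, biases on.  Padding 1 is the only convention under which an
input of 512 maps to exactly 16 per side (each layer computes
⌊(n+2−4)/2⌋+1 = n/2).  The receptive field follows
rf_k = rf_{k−1} + (kernel−1)·∏ previous strides: 4 → 10 → 22 → 46 → 94.
Both facts are verified empirically (forward shapes for random sizes; the
gradient-support footprint of a central score unit).

### EGAN generator

Encoder: stem (3×3, stride 2) then seven MBConv blocks
(expand 1×1 → depthwise k×k → squeeze-excitation → project 1×1, batch
normalization after every convolution, swish activations, residual shortcut
when stride 1 and channels match).  Base skeleton
(expand, channels, repeats, stride, kernel): (1,16,1,1,3), (6,24,2,2,3),
(6,40,2,2,5), (6,80,3,2,3), (6,112,3,1,5), (6,192,4,2,5), (6,320,1,1,3);
SE reduction 0.25 of block input channels.  Compound scaling uses
α = 1.2, β = 1.1, γ_r = 1.15 (α·β²·γ_r² = 1.92, accepted within tolerance
0.1 of 2) with default φ = 4: channels multiply by β^φ (rounded to multiples
of 8), repeats by ⌈α^φ·n⌉.  The resolution multiplier is honoured as a
config default only — training happens at a fixed working resolution.

Decoder: four stages, each bilinear-upsample → concatenate one lateral
encoder feature → two 3×3 conv + BN + swish; stage widths 320/160/80/40;
head = bilinear to input size → 1×1 conv → sigmoid.  Laterals are *skewed*:
only the four blocks where the encoder changes resolution (blocks 5, 3, 2, 1
at 1/16, 1/8, 1/4, 1/2) feed the decoder, one per stage, rather than a
symmetric one-per-block mirror.  With these defaults the generator counts
26.92M trainable parameters at any input size (fully convolutional).  The
27M total is the architecture's defining budget; per-block widths are design
choices made once to land on that total, with the seven-block SE-MBConv
skeleton fixed.

### MGAN generator

Encoder: MobileNetV2 stage layout (expand 6 except the first stage), width
multiplier 0.75, channels rounded to multiples of 8.  The two stages that
would naturally stride to 1/16 and 1/32 instead run at stride 1 with
dilations 2 and 4, giving output stride 8 — the standard semantic-
segmentation modification that preserves the enlarged receptive field.
ASPP over the deepest feature: branches at rates 1 (as 1×1), 6, 12, 18
(3×3, padding = rate), each conv + BN + ReLU at width 128, concatenated and
projected to 128.  No global-pooling branch (only the four dilation rates
are part of the design).  Decoder: the 1/2-resolution stage output is
projected to 48 channels, the ASPP output is bilinearly upsampled to it,
both are concatenated and refined by two 3×3 convs at width 96, upsampled to
input size, 1×1 + sigmoid.  Total: 2.209M parameters — 8.2% of EGAN.

Dilated branches use zero padding, so they operate on feature maps smaller
than their nominal kernel support (e.g. the 16×16 deepest feature of a
128×128 input); the far taps then read zeros and the branch degrades
gracefully toward a local filter, which is the behaviour that makes
reduced-resolution training runs possible.

## Training procedure

Adam with learning rate 2e−4 for both players, β = (0.5, 0.999) —
conventional patchGAN settings; constant schedule.  λ_adv defaults to 1.0
(the combined loss is printed without an adversarial weight, so the weight
is exposed rather than hard-coded); λ_adv = 0 is the supervised ablation.
Per batch, one discriminator step precedes one generator step; each full
cycle updates each parameter set exactly once, and the generator's output is
detached during the discriminator step while discriminator gradients are
computed but discarded during the generator step.  20% of the data is held
out for validation (the split fraction the framework was designed with); the
generator with the best validation dice is checkpointed and returned.
A run is a pure function of (manifest, config, seed): the seed drives
parameter initialization, the train/validation split and the batch order.
Non-finite losses abort with a diagnostic rather than continuing silently.

The working resolution is 512×512 for full-scale models (the resolution the
architectures were designed around); the packaged experiments run at 64–128
pixels with width-scaled models, which keeps a full 30-epoch adversarial run
on 100 scenes within minutes on one CPU core while exercising every code
path of the full-size models.

## Synthetic scenes

`generate_scene(params, seed)` renders: (1) a pinkish skin background with
small per-image colour jitter; (2) one lesion — an ellipse-like region whose
radius is modulated by normalized low-frequency harmonics (orders 2–6,
amplitude = `boundary_roughness`), darker than skin by exactly
`contrast_delta` per channel, with a 1-pixel anti-aliased rim; (3) a
multiplicative radial vignette; (4) `hair_count` dark quadratic-Bézier
streaks of width `hair_width` drawn over skin and lesion; (5) additive
Gaussian noise.  The mask is the binary lesion region *before* hair
occlusion.  Lesion area is rejection-sampled into `lesion_area_range`
(default 5–35% of the image), with a bounded retry budget.  Defaults
(contrast 0.35, roughness 0.15, 3 hairs, vignette 0.25, noise 0.03) are
chosen to resemble moderately difficult dermoscopy.

What the generator does *not* emulate: multi-lesion images, specular
reflections, colour charts/rulers, gel-interface artifacts, true skin
texture, and lesions with internal structure (networks, globules).  Passing
the packaged experiments therefore shows that the optimization and
architectures work end to end on controlled data with the stated nuisance
factors — not that the models reach any particular accuracy on clinical
dermoscopy.

## Numerical choices

- float32 everywhere in the network path; loss reference evaluations on
  plain arrays run in float64 so they agree with brute-force oracles to
  1e−10.
- ε = 1e−7 for the dice denominator and score clamping; sigmoid inputs
  clipped at ±60 before exponentiation.
- Bilinear resampling uses half-pixel-centred sampling and exactly preserves
  constant fields; masks are resized nearest-neighbour so they stay binary.
- Mask binarization threshold: 8-bit 128 (midpoint convention); prediction
  threshold 0.5 with ties (ŷ = threshold) mapped to foreground.
- Empty-denominator metric convention: 1 when both masks are empty of the
  relevant class, else 0; metrics are per-image-then-averaged (pooled-pixel
  variant also reported).  Metrics are computed at the working resolution
  the generator ran at, stated in the report header.
- Parameter initialization: fan-in-scaled normal (std = √(2/fan_in)), biases
  zero, from one seeded generator.

## Known limitations

- CPU-only NumPy execution: full-width 512×512 training is functional but
  slow; the intended full-scale use is the reduced-width/reduced-resolution
  regime demonstrated in the examples and tests.
- The smoothing loss as defined is one-sided (foreground only) and grows
  with lesion perimeter; the normalized variant mitigates but does not
  remove the scale dependence.
- Batch-normalization statistics are per-run; very small batches at tiny
  test widths can make early validation scores noisy.
- The discriminator judges masks without the conditioning image, so it can
  only enforce shape plausibility, not image-mask consistency.
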