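# Methods

This note documents the models, the synthetic data, the numerical
choices and the limitations of the `pseudohealthy` package. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Problem setting and assumptions

A pathological 2-D slice p with binary lesion annotation y (1 =
pathological) is mapped to a pseudo-healthy slice ĥ such that (i) ĥ
looks like it was drawn from the healthy-image distribution and (ii)
ĥ equals p outside the lesion region. The central assumption is that
pseudo-healthy synthesis can be cast as *inpainting*: erase the lesion
(plus a 5 mm perilesional margin) and fill it from healthy context.
Identity preservation is then not a learned property but a structural
one — the final composite `m⊙generated + (1−m)⊙input` is bit-exact
outside the mask, and the masked PSNR/SSIM identity metrics hit their
caps by construction (this is a hard regression test, not an empirical
finding).

Training uses healthy slices only; the training loader rejects any
item accompanied by a nonempty ground-truth lesion mask. Lesions are
simulated at train time by random masks covering 30–60 % of the brain
area, which stands in for a segmentor detecting lesions at inference.

## Stage 1 — localization

A standard encoder–decoder U-Net with skip connections, pixel-wise
binary cross-entropy, Adam, and a 0.5 decision threshold. Default
architecture: depth 4, base width 32. The desk-scale study uses depth
3 / width 8 at 64×64, which the `config` argument exposes. The
predicted mask is dilated with a Euclidean disk of radius
`margin_mm / spacing` pixels (default 5 mm); this dilated mask drives
the coarse fill, the refinement and the composite. Manual pixel-level
annotations can replace the model anywhere a mask is accepted.

The Healthiness metric's segmentation model f_p is the same class,
trained separately (different seed) from the localization instance so
the metric does not simply reuse the pipeline's own localizer.

## Stage 2 — coarse fill (Vague-Filler)

Input: the masked image concatenated with the mask (two channels).
Architecture: gated convolutions only — each layer computes
`ELU(conv_f(x)) ⊙ σ(conv_g(x))` — in a straight line with no cross-scale
skip connections: a stride-2 5×5 gate to H/2, a stride-2 3×3 gate to
H/4, a widening gate (channel plan `w → 2w → 4w`, default w = 32), six
dilated gated blocks at H/4 with dilations 1, 2, 4, 8, 4, 2 (each a
local residual `x + block(x)`), an upsample to H/2 with a gated conv,
and a tanh head *at H/2* followed by a fixed nearest ×2 upsample and a
3×3 binomial smoothing kernel.

The tail is the package's deliberate design: the coarse fill is
band-limited at the H/2 scale *by construction*. The division of
labor intended by the three-stage design is that stage 2 recovers
contours with high tolerance for texture (hence the L1-only loss,
which penalizes structure more than sharpness) and stage 3 owns
full-resolution detail. With learnable full-resolution convolutions in
the filler tail, the "vague" fill stops being vague and the refinement
stage has nothing left to add.

Loss: mean absolute error against the intact healthy slice over all
pixels and batch items. Output is composited with the input, so the
filler never alters pixels outside the mask, and the network never
reads masked pixels (its image channel is pre-multiplied by 1−m).

## Stage 3 — refinement (flip-symmetric contextual residual attention)

Input: the coarse fill and the mask. Both the input and its
horizontal mirror are encoded by shared weights (5×5 stride-1, then two
3×3 stride-2 convs, ELU; channel plan default 16/32/48) down to H/4.

**Attention calculation.** The deepest features are tiled into
non-overlapping patches — 16×16 *image* pixels per patch, i.e. 4×4
feature cells; at the default 256×256 attention resolution this yields
a 16×16 grid of 256 patches and a 256×256 score matrix. A patch is
*inside* (hole) if any of its pixels is masked — a conservative rule
that guarantees no lesion pixel ever serves as context. Cosine
affinities between context and hole patches are squared and normalized
per hole column, giving a column-stochastic, convex weighting (every
filled patch lies in the convex hull of context patches). Norms are
guarded by ε = 1e−8; a hole column whose affinities are all ~0 falls
back to uniform weights over context, so degenerate masks cannot
produce NaNs. If the mask leaves no context patch (or no hole patch),
attention is skipped entirely and the decoder works alone.

**Fusion and decoding.** Four streams are concatenated — forward
features, re-flipped mirror features, attention-filled forward
features, re-flipped attention-filled mirror features — and fused by a
3×3 conv, decoded by two upsample+conv stages, then a full-resolution
3×3 conv that also receives the stride-1 encoder features of both
orientations (the refiner's source of genuine full-resolution detail),
and a tanh head.

**Merge.** Inside the mask the output is

    vague + tanh-correction + g · (R_agg − R),

where R is the high-frequency residual of the coarse fill
(`x − up(down(x))` with block-average down / nearest up at factor 4),
R_agg is the attention-weighted transplant of context residual patches,
and g is a learned scalar gate initialized at 0. With g = 1 this is
exactly "blurry base + transplanted residual + correction"; with g = 0
the transplant is off. The gate exists because transplant quality
depends on how distinctive the context patches are: on smooth synthetic
tissue the attention columns are near-uniform and a forced transplant
would *replace* the filler's accurate residual with a near-zero average;
training sets the transplant strength instead. Outside the mask the
input is kept bit-exactly.

**Exact flip equivariance.** Decoder and fusion kernels are
width-symmetrized at forward time (`W ← (W + flip_w W)/2`); the fusion
and full-resolution convs are additionally symmetrized under the
channel-group permutation induced by swapping the forward/mirror
streams. Together with the attention module's intrinsic mirror
equivariance this makes `refine(flip x, flip m) = flip(refine(x, m))`
exact to float precision. One consequence is forced: when the flip path
is active, residual aggregation uses the symmetrized scores
`(S_forward + mirror-permuted S_mirror)/2` — with the forward-path
scores alone, the two paths swap roles under a flip and equivariance
breaks. The two matrices coincide whenever attention is
mirror-consistent, so this is the canonical equivariant completion, not
a change of mechanism.

**Ablation switches.** `use_cra=False` reduces the model to a plain
encoder–decoder (no attention streams, no residual transplant);
`use_flip=True` requires `use_cra`. The fusion columns that receive the
attention-transfer streams are zero-initialized, so switching CRA on
never degrades the baseline function at initialization — the streams
are recruited only where they reduce the loss. Without this, at small
equal budgets the extra initially-uninformative streams slow the +CRA
configuration below the plain baseline, which inverts the expected
ablation ordering for reasons of optimization speed, not of mechanism.

## Adversarial objectives

The critic is a five-layer strided spectral-normalized conv stack
(one power iteration per forward; the norm is treated as constant in
the backward pass), mean-reduced to a scalar score per sample. Hinge
losses: `L_D = E max(0,1−D(real)) + E max(0,1+D(fake))`,
`L_G = −E D(fake)`; scores beyond the ±1 margins contribute zero
gradient. The perceptual term is `λ/K Σ_k E |φ_k(h) − φ_k(ĥ)|` over
K = 3 tap layers of a frozen feature extractor, λ = 64. The default
extractor is "random-fixed": a seeded, never-trained conv stack with
average-pool stages — deterministic and self-contained. A VGG16
backbone can be plugged in from a local `.npz` weights archive; no
weights ship with the package.

## Training procedure

Two phases. Phase A trains the filler alone (L1). Phase B freezes the
filler and alternates critic/generator updates on freshly masked
healthy slices: per step, sample masks (30–60 % of brain), coarse-fill,
refine, update D with the hinge loss on real slices vs composited
fakes, update G with `L_G + L_perc`. Adam with initial learning rate
0.001 halved every 5 epochs for all models. Default batch: 16 for
slices up to 256 px, 4 at 512 px; the desk study uses batch 8 (phase B)
and 4 (phase A), where one epoch over 200 slices is 25–50 steps, so the
decay pace in steps is comparable to the published-scale setting.

Every run is a pure function of its seed: numpy `default_rng`
throughout, no hidden global state; repeated runs are bit-identical.

## Synthetic phantoms

`make_healthy_phantom` draws a bilaterally symmetric "brain": an
elliptical foreground (default semi-axes 0.40/0.34 of the image) on a
−1 background, a brighter cortex band, mirrored pairs of internal
tissue ellipses with random intensities, ventricle-like dark shapes,
and smoothed Gaussian noise (default σ = 0.03) added inside the
foreground. With σ = 0 a phantom equals its mirror exactly — the
symmetry budget that the flip path exploits.

`inject_lesion` applies a circular intensity anomaly (shift ∈ [−2, 2],
with proportional texture, so a zero shift changes nothing) and an
optional *mass effect*: a radially decaying outward displacement of
peak amplitude A/2 with compact support just under A pixels wide, so
the image provably changes only within the lesion disk dilated by A.
Amplitudes below one pixel are treated as no deformation.

`sample_training_mask` unions random thick polylines and disks, then
grows or shrinks the union monotonically — ranking foreground pixels by
signed Euclidean distance to the union and thresholding at an exact
pixel count — until the masked fraction of the *brain* (not the image;
on skull-stripped data image-relative fractions above ~40 % are
unreachable) equals a target drawn uniformly from [0.30, 0.60].

Default study conditions: 250 phantoms at 64×64 (200 train / 50 held
out), lesion radii 9–19 % of the image, intensity shifts ±0.5–1.0,
deformation amplitudes 0–3 px (2.5–5 px for the deformation-classifier
cohort), 200 filler steps, 500 adversarial steps per generator
configuration, generator patch size 8 (an 8×8 patch grid; at the
default 16-px patch a 64-px image would have only 16 patches and
the 30–60 % masks would leave no context).

**What the phantoms do not emulate** — and hence what passing tests do
not show about real data: MR physics (no bias fields, no Rician noise,
no partial-volume effects), realistic anatomy (no gyri/sulci, no
texture at the scale attention exploits on real scans), 3-D context,
multi-modality, and realistic lesion appearance heterogeneity. In
particular, phantom tissue is locally smooth, so attention affinities
are nearly uniform and the residual-transplant mechanism contributes
less than it would on textured clinical images; conclusions about the
*relative* value of CRA at desk scale transfer to clinical scale only
as a trend.

## Evaluation suite

* **Healthiness** `H = 1 − E N(f_p(ĥ)) / E N(f_p(p))`, a ratio of
  means (matching the nested expectations of its definition), using
  f_p's own segmentation of the inputs rather than the true masks to
  cancel segmentor bias. Errors if f_p finds no pathology in the
  inputs.
* **Masked PSNR**: images rescaled to [0, 1], MSE over the mask
  complement only, peak 1, capped at 99 dB for identical regions.
* **Masked SSIM**: single-scale SSIM (11×11 Gaussian window, σ = 1.5,
  standard stabilizers) on images with the masked region zeroed on both
  sides, matching the metric's `(1−y)⊙` definition literally.
* **Structure Healthiness**: Canny edge maps (σ = 1, hysteresis at the
  10th/30th gradient-magnitude quantiles — percentile thresholds chosen
  for intensity-scale robustness), a VGG-style conv classifier trained
  with BCE on healthy vs mass-effect-deformed phantom edge maps, and SH
  = the mean deformation-free probability over outputs synthesized from
  inputs whose lesion *strictly* exceeds 20 % of the brain area.

At desk scale the reported masked PSNR uses the ground-truth lesion
mask while the pipeline replaces the *segmented* lesion plus 5 mm;
segmentation overshoot therefore counts against identity, which is the
realistic reading of the metric. SH is low for inputs and outputs
alike because mass-effect deformation beyond the 5 mm margin is —
correctly — preserved by the identity contract.

## Numerical choices

float32 tensors throughout; ε = 1e−8 in cosine norms; uniform fallback
for all-zero affinity columns; logits clipped at ±60 before sigmoids;
zero-range images normalize to −1 everywhere (the background
convention for skull-stripped data); masks are strictly {0, 1};
dilation uses the exact Euclidean lattice disk (`dx²+dy² ≤ r²`);
coordinates are 0-based row-major and flips are about the vertical
midline. The spectral norm's backward pass treats the norm as a
constant — the standard approximation. Checkpoints are single-file
`.npz` archives holding an architecture id, JSON metadata and the
parameter arrays in construction order.

## Known limitations

* The numpy engine is single-threaded per op and desk-scale only;
  clinical-scale training (thousands of 240×240 slices, batch 16) is
  out of reach on CPU and published benchmark scores are not reproduced
  here.
* The generator processes one sample per forward internally (attention
  matrices are per-sample); batching loops over samples.
* The ablation ordering (plain GAN ≥ +CRA ≥ +CRA+FLIP on masked L1) is
  asserted for the fixed-seed study; at these budgets the GAN-vs-+CRA
  margin is within run-to-run variation across seeds, while the flip
  path's advantage is robust on the symmetric phantoms.
* `vague_fill`/`refine` require dimensions divisible by 4 and by the
  patch size respectively; 240×240 clinical slices are resized to
  256×256 (bilinear) before the generator and back afterwards so the
  16-px patch arithmetic is exact.
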