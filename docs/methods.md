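# Methods

## Problem setting

The classifier identifies the cultivar (and implicitly the origin) of a
flower specimen from a *pair* of RGB photographs — one of the front of the
inflorescence, one of the back. The motivating observation is that
discriminative information is split across the two sides: ray-floret shape,
color and center-disk size on the front; calyx rings, bract arrangement and
receptacle on the back. Two cultivars may coincide on one side and differ
on the other, so any single-view classifier has an intrinsic accuracy
ceiling, while a fused-view classifier does not.

## Architecture

Each stream is a ResNet-18-style backbone: a 7×7 stride-2 stem conv (64
channels), a 3×3 stride-2 max-pool, then four stages of two basic blocks
with channel plan 64/128/256/512 — 17 conv layers per stream. For a
224×224×3 input the stage outputs are 112²×64, 56²×64 (pool), 56²×64,
28²×128, 14²×256, 7²×512, then 1×1×512 after global average pooling; the
FC chain is 512→128→32 per stream, a 64-d concatenation, and a final FC to
the class logits.

**Residual blocks carry no post-addition activation.** A block computes
exactly `h(x) + F(x)` with the nonlinearity inside
`F = conv–BN–ReLU–conv–BN` (a pre-activation-style choice). This keeps the
block's output identical to the additive update rule, so the degenerate
algebra — `F ≡ 0` ⟹ output equals the shortcut sum — holds to machine
precision and is asserted in the tests.

**Cross-stream residual connections** live in the final (512-channel)
stage, i.e. in the "deep feature fusion" part (the last 4 conv layers):
both blocks of that stage compute, per stream `p` (sibling `q`),
`out_p = h(x_p) + h(x_q) + F(x_p, W_p)`, both streams updating
synchronously from the pre-update inputs. The first block of the stage
changes resolution and channels; its shortcut is a per-stream 1×1 stride-2
projection applied to the *summed* identity inputs, `project_p(x_p + x_q)`,
which preserves the symmetric form of the cross-stream sum with minimal
extra parameters.

**Weighted FC fusion** applies at the inputs of both per-stream FC layers:
`out_p = G_p(y_p + α·y_q)` with own-to-cross ratio 1:3 (α = 1/3) by
default; the final 64→classes layer fuses by plain concatenation. α is
configurable (the ablation grid sweeps 1, 1/2, 1/4, 1/3, and 0 reproduces
independent streams bit-exactly). The two streams share no weights; batch
normalization statistics are per-stream.

With unshared streams the canonical 18-class model counts ≈22.5 M trainable
parameters (measured at build time by the acceptance script). Published
descriptions of this architecture sometimes quote ≈13.4 M; that figure is
not reproducible from the stated layer dimensions without a weight-sharing
scheme no description specifies, so the parameter count is reported but not
treated as a reference value.

## Preprocessing

Five steps per view: (1) Canny edge detection on the ITU-R 601 luminance
image (thresholds 50/150 on the 8-bit scale — common defaults that suit
high-contrast flowers on studio backgrounds; Gaussian sigma 1); (2) crop to
the minimal axis-aligned square containing the bounding box of all edge
pixels, centered on the box and shifted inward at image borders, never
padded — an empty mask leaves the image unchanged and the side never drops
below 8 px (speckle guard); (3) resize to the square network input
(224 default; aspect ratio not preserved); (4) during training only,
random rotation uniform in ±15° (bilinear, black fill), applied after the
resize, with independent angles per view by default and a flag to lock
them; (5) normalization `(pixel/255 − mean)/std` per channel, defaulting to
the ImageNet statistics because the canonical recipe transfers
ImageNet-pretrained shallow weights.

## Training protocol

Stage 1 freezes the 13 shallow conv layers per stream (stem + stages 1–3,
including their BN *parameters*; running statistics keep updating) and
trains the deep part for 20 epochs at lr 1e-3, batch 24, Adam,
cross-entropy. Stage 2 unfreezes everything and fine-tunes for 30 epochs at
lr 1e-4. "Epoch" here means one pass over the training set with validation
after each pass; the best-validation-accuracy checkpoint is kept, so the
returned model is never worse on validation than the final epoch. Adam's
betas/eps stay at framework defaults; no LR scheduler within a stage. SGD
(momentum 0.9), RMSprop and NAdam are available behind a config switch for
optimizer comparisons; Adam is the default.

Shallow initialization accepts a caller-supplied transferred-weight file;
offline, a seeded random fallback re-draws the shallow layers so the staged
protocol remains runnable without any download.

The experiment protocol repeats (fresh 6:2:2 stratified split → fresh init
→ staged training → test evaluation) n times — 50 in the canonical setup —
and aggregates the per-repeat metrics. All three splits are re-randomized
each repeat; per-repeat seeds derive from the run seed as
`seed + repeat_index`. Split rounding is `floor(0.6 n)` / `floor(0.2 n)` /
remainder-to-test per class, which is deterministic and keeps the test
split non-empty.

## Metrics

Accuracy = trace/total of the confusion matrix; per-class recall =
diagonal/row sum; per-class precision = diagonal/column sum (0 for empty
columns). Recall and F1 are macro (unweighted class means) — consistent
with reporting single values over many balanced classes — with weighted
averaging behind a flag. Inter-class stability is the *population* standard
deviation of per-class recall, expressed in percentage points. Average
inference time is wall-clock per single-sample forward pass (batch 1,
warm-up discarded); it excludes preprocessing, is hardware-dependent, and
is never used as a reference value. Argmax ties break to the lowest class
index for determinism.

## Synthetic data generator

The generator renders flower-like view pairs from discrete cue vectors:
front = (petal count, petal hue, center-disk radius) drawn as a rosette of
disjoint elliptical petals around a central disk; back = (calyx ring count,
calyx hue, bract spokes) drawn as concentric rings, a receptacle disk, and
a ring of spokes. Flowers sit on a dark plain (or optionally textured)
background so edges are well defined. Per-sample nuisance variation
(whole-flower rotation, brightness) is seeded by (view-cue, sample index):
classes that share a view's cues produce *pixel-identical* renders of that
view up to additive Gaussian pixel noise (σ = 8 on the 8-bit scale by
default), so the shared view carries exactly zero extra information.

The overlap plan pairs classes (0,1), (2,3), … identically on the front and
the shifted pairs (1,2), (3,4), … identically on the back, so no pair
coincides on both views and the joint cue vector stays unique.
`bayes_separability` computes the exact single-view accuracy ceilings by
enumeration: with uniform priors, (number of distinct cue vectors)/
(number of classes). The desk-scale conditions — 6 classes × 20 pairs at
64×64, overlap 2/3 — put both single-view bounds at 2/3 with a joint bound
of 1.0.

What the generator does *not* emulate: natural texture, lighting variation,
occlusion, petal damage, background clutter, and the soft intra-class
morphological variation of real cultivars. Passing tests therefore
demonstrate that the architecture, fusion math, training loop and metrics
behave as specified and that fusion recovers information genuinely split
across views — not that real-photograph accuracy levels are reproduced.

## Problem sizes and profiles

The canonical profile (224×224 inputs, full channel plan, 20+30 epochs,
batch 24) matches the published recipe and is the default for real runs.
All tests and the acceptance script use the desk-scale profile: 32×32
inputs, channel plan (8, 8, 16, 32, 64), FC dims (32, 16), batch 8,
5+10 epochs at lr 3e-3/1e-3 — learning rates raised in proportion to the
much shorter schedule — and 3 repeats per condition. On this profile one
staged training takes a few seconds on one CPU core with the bundled numpy
engine.

## Numerical choices

- Convolution via im2col + matmul, float64 throughout; no bias terms on
  convs (BN follows every conv).
- BN eps 1e-5, momentum 0.1; in eval mode running statistics are used.
- He-normal conv initialization, uniform ±1/√fan_in for FC layers, all from
  a single seeded generator in construction order, so two builds with the
  same seed are bit-identical.
- Cross-entropy clips probabilities at 1e-300 before the log.
- Non-finite training loss aborts with a diagnostic rather than continuing.
- Degenerate crops: empty edge mask → full image; mask bounding box larger
  than the shorter image side (only possible on non-square images) → the
  square is clipped to that side and centered, a documented best-effort.
- Checkpoints serialize all arrays plus the model spec, label ordering and
  preprocessing config, and round-trip bit-exactly.

## Visual analyses

Plain class-activation mapping is ill-defined here (three FC layers
separate the final conv features from the logits), so the gradient-weighted
variant is used: channel weights are spatially averaged gradients of the
target class score at each stream's final conv stage; the rectified,
min–max-normalized map is upsampled to the input size. Note the desk-scale
profile's final stage is 1×1 at 32-px inputs — for spatially meaningful
maps, feed a larger preprocessed input (the network is fully convolutional
up to the global pool). The t-SNE embedding uses the fused 64-d vector (the
concatenation fed to the final FC), with per-stream 32-d vectors available
as an option; perplexity adapts to min(30, (n−1)/3) and the embedding is
seeded.

## Known limitations

- No real-photograph dataset ships with the package; the published
  headline accuracies on 18 real cultivars are not reproducible here and
  are not claimed.
- The numpy engine is single-threaded BLAS-bound; the canonical 224 profile
  trains orders of magnitude slower than a GPU framework would and is
  practical mainly for inference-scale checks.
- Image-quality screening of raw photographs (a human judgment step in
  real acquisitions) is out of scope; the manifest is trusted as-is.
- Rotation augmentation rotates around the image center only; no other
  augmentations are implemented.
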