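# Methods

## The two-stage model

**Stage 1 (semantic).** The stacked U-Nets (SUNets) model consists of four
parallel backbone networks, one per pyramid scale (1.25×, 1.0×, 0.75×,
0.5× of the base patch side; the four factors are fixed). Each backbone is
a U-Net with a VGG-style encoder: `depth` blocks of two same-padded 3×3
convolutions + ReLU followed by 2×2 max pooling, channel widths doubling
from `base_width` and capped at `8·base_width`; the decoder mirrors it with
2×2 transposed convolutions and skip copy-and-concatenation; a 1×1
convolution emits one logit per pixel. The four logit maps are bilinearly
resampled to the base resolution and concatenated into the attention
generation module (AGM): a 3×3 stem convolution, eight further 3×3
convolutions arranged as four identity-skip residual blocks (two
ResNet-34-style stages of two basic blocks), and a 1×1 head producing four
maps. A per-pixel softmax turns these into weights `w_k ≥ 0, Σ_k w_k = 1`;
the fused probability is `σ(Σ_k w_k z_k)`.

Two architectural points were genuinely open and were resolved as follows:

* *What the AGM consumes.* The AGM is fed the four resampled single-channel
  prediction (logit) maps rather than deep feature maps. This keeps the
  module scale-agnostic, matches the "weight and sum the predictions"
  reading of the fusion step, and makes the weight maps directly
  interpretable as per-scale votes.
* *Weight normalization.* The per-pixel softmax makes the fusion a convex
  combination, which gives the invariant the tests check (weights sum to 1
  everywhere) and keeps the fused logit on the scale of the per-net logits.

Backbones have identical architecture but independent parameters. Scaled
levels whose side is not divisible by `2^depth` are reflect-padded before
the backbone and cropped after it (gradients flow through the reflected
indices); a backbone called directly with an indivisible size raises a
shape error.

**Stage 2 (overlap).** The identical architecture with a 4-channel input:
RGB plus the binary nucleus mask, scaled to {0, 255} on disk and {0, 1}
inside the network. During training the ground-truth semantic mask is used
as the fourth channel (teacher forcing); at inference the stage-1
prediction takes its place. Teacher forcing decouples the two stages'
training while matching the stated inference flow; the alternative
(training on predicted masks) would couple stage-2 data generation to a
trained stage-1 model without changing what stage 2 must learn.

**Losses.** Stage 1: mean binary cross-entropy with probabilities clamped
to `[1e-7, 1-1e-7]`. Stage 2: mean focal loss
`−α_t (1−p_t)^γ log p_t`, `p_t = p` for positive pixels and `1−p`
otherwise, `α_t = α` / `1−α` likewise. `γ = 2, α = 0.25` are the library
defaults (the canonical values); at `γ=0, α=0.5` the focal loss reduces
exactly to half the cross-entropy, which the tests exploit. Gradients are
taken analytically with respect to the pre-sigmoid logit.

**Optimization.** Plain SGD with classical momentum (`v ← m·v + g`,
`θ ← θ − lr·v`), constant learning rate, batch shuffling and one random
right-angle rotation / flip per sample per epoch (the identity is always a
candidate, so augmentation never forces a transform). The reference recipe
(lr 1e-4, momentum 0.9, batch 4, 20 epochs, 384×384 inputs) is the
`TrainConfig` default.

## Numerical implementation

The layers are a small numpy framework written for this package:
convolutions are lowered to BLAS matrix multiplies via im2col, the 2×2
transposed convolution and max pooling use reshape tricks, and bilinear
resampling is implemented as a pair of dense interpolation matrices
`y = R x Cᵀ`, whose backward pass is the exact transpose `Rᵀ g C`. All
parameters and activations are float32. Backward passes were verified
against central finite differences (per-parameter and directional
derivatives). Single-threaded runs are bit-reproducible; layers skip their
backward caches inside inference so prediction is cheap in memory.

## Instance extraction and merging

The thresholded (p ≥ 0.5) stage-1 mask is split by a marker-based
watershed: markers are the **h-maxima of the Euclidean distance
transform** with prominence `h = 0.5` px, i.e. local maxima that rise at
least `h` above the saddle connecting them to a higher maximum. The
flooding runs on the negated distance restricted to the mask; objects
below `min_size = 20` px are dropped. The prominence rule was chosen over
a fixed fraction of the per-component maximum distance because the latter
cannot form a marker for a small nucleus fused to a much larger one (its
peak always sits below any useful fraction of the component maximum), and
it over- or under-splits depending on component geometry: for two equal
r = 15 disks with centers 24 px apart the neck distance is 9 while the
peaks are 15, so any threshold in (9, 15) separates them — but that window
shifts with every shape. Prominence is geometry-independent: a single
convex nucleus (one maximum, up to sub-pixel plateau ripple well below
0.5 px) yields exactly one marker, and any pair of cores whose saddle dips
at least 0.5 px below both peaks is split.

Stage 2's thresholded overlap mask is decomposed into 8-connected
components; each component is unioned into **every** instance it
intersects by at least `min_overlap = 10` pixels, and components reaching
no instance are discarded. The threshold is strict (9 shared pixels do not
merge). Merging only ever adds pixels; overlap pixels may therefore belong
to several final instances, which is exactly how ground truth represents
two nuclei sharing pixels. Final instances are stored as per-object masks
(lossless run-length CSV); the flattened 16-bit PNG rendering assigns
shared pixels to the lowest label id.

## Metrics

AJI matches every ground-truth object to the predicted object maximizing
the Jaccard index (ties → lowest predicted label id; a ground-truth object
intersecting nothing contributes its own area to the denominator), sums
matched intersections over matched unions, and adds the areas of unmatched
predicted objects. The default unmatched set `U` is *predictions that
intersect no ground-truth object*; a `used_flag` variant (predictions
never selected as a best match — the original AJI bookkeeping, which also
penalizes matched-but-unused predictions) is available as a switch. A
brute-force re-derivation over explicit pixel sets serves as the oracle in
tests; the fast path accumulates exact integer counts so the two agree to
the bit. Degenerate conventions: both maps/masks empty → 1; exactly one
empty → 0. Set-level scores are unweighted per-image means. Overlapping
final instances are evaluated object-wise, never via the flattened
rendering.

## Synthetic data

Each scene draws `n_nuclei` rotated ellipses with semi-axes uniform in
`radius_range` (default 5–9 px on a 64×64 canvas, roughly the relative
nucleus size of the benchmark patches). With probability
`overlap_fraction` a nucleus is centered within one minor-axis diameter of
a random existing nucleus — placement is accepted only if the pixel masks
actually intersect — otherwise placement must be disjoint from all
existing nuclei; either mode retries up to 200 times before reporting a
generation error with the achieved count. Rendering is subtractive:
starting from the eosin-like background (230, 200, 215), every nucleus
subtracts its attenuation (background minus a per-nucleus jitter of the
hematoxylin-like color (90, 60, 150)), so doubly covered pixels are
visibly darker — the physical Beer–Lambert cue that makes overlap regions
learnable from intensity alone; Gaussian noise (σ = 8) is added last and
the image clipped to 8 bits. Ground truth is exact by construction:
per-nucleus masks, their union, and pixels covered at least twice.

What the generator does **not** emulate: chromatin texture, stain
variation between slides, non-elliptical or lobulated nuclei, clusters of
three or more mutually overlapping cells beyond what random placement
produces, and out-of-focus blur. Passing tests on this data demonstrates
that the pipeline's mechanics (learning, fusion, watershed, merging,
scoring) work end to end, not that the model reaches benchmark accuracy on
real tissue.

## The scaled-down experiment

`run_demo` / `sunseg demo` trains both stages from scratch on CPU: tiny
networks (base width 8, depth 3) on 64×64 patches, 200 training scenes
with `overlap_fraction = 0.5`, 25 held-out scenes, 2 epochs per stage,
batch 4, momentum 0.9. The learning rates differ from the full-scale
recipe because 100 SGD steps from random initialization need far larger
steps than 20 epochs over a large dataset: stage 1 uses 0.02 (cross-
entropy; larger rates destabilized some initializations), stage 2 uses
0.05 with `α = 0.75` (focal gradients are much smaller, and at ~3%
positive pixels the canonical α = 0.25 lets the net collapse to the
background class). The demo reports per-image and overall AJI, pixel
precision/recall/F1, the AJI between true and predicted overlap-region
components, and the pooled recall of true overlap pixels by multi-assigned
pixels with and without stage 2 — pooled over the whole test set, because
per-image averaging would credit the stage-1-only baseline on scenes that
happen to contain no overlap at all. Typical seeds reach overall AJI
0.52–0.63 with semantic F1 ≈ 0.96–0.99; the two-stage overlap recall is
0.14–0.18 versus exactly 0 for the single-stage pipeline (disjoint
instances cannot multi-assign a pixel).

## Known limitations

* Nearly concentric or deeply fused nucleus pairs are irrecoverable from a
  binary mask: no distance-transform marker scheme can separate a nucleus
  whose core lies inside another's. This caps object-level AJI on scenes
  with heavy overlap even when the semantic mask is almost perfect.
* The merge rule annotates shared pixels but never *splits* a fused
  stage-1 blob into two instances, so a pair the watershed missed stays
  one object even when stage 2 finds their shared region.
* Training is CPU-bound numpy: the full-scale configuration (width 16,
  depth 4, 384×384) runs, but at speeds suited to small experiments, not
  to benchmark-scale training.
* The evaluate subcommand reads flattened label maps, which lose shared
  pixels; library-level evaluation on per-object masks is exact.
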