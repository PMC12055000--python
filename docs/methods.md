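# Methods

This note documents the models, algorithms and numerical choices behind
`adpt`: what each component computes, the defaults and their units, what
the synthetic fixtures do and do not emulate, and where the design was
genuinely open.

## Geometry and coordinate conventions

All coordinates are 0-based pixels, origin at the top-left, x rightward,
y downward, with a keypoint sitting at a pixel center. Annotation tables
always store full-resolution coordinates; the `global_scale` resize
(default 1.0, set to e.g. 0.5 for large video frames) is applied
internally before encoding and undone after decoding, so file round trips
are exact. A NaN or absent table cell means "not annotated" (visibility
0), never the coordinate (0, 0).

All four network heads share one output grid of shape
`(ceil(H/stride), ceil(W/stride))` with stride 8 (a power of two,
configurable). Head cell `(r, c)` represents the image point
`(c·stride, r·stride)`; a keypoint `p` maps to `p/stride` in grid units.

## Target encoding

**Confidence heatmaps.** Channel k holds
`max_instances exp(−d²/2σ²)` where `d` is the grid-unit distance from the
cell to the keypoint; σ defaults to 3 cells (desk-scale configs use 1).
The cell nearest each visible keypoint is forced to exactly 1. This
deliberate departure from a pure Gaussian (which peaks below 1 for
off-grid keypoints) gives two properties the tests rely on: a perfect
prediction decodes with confidence exactly 1, and the argmax cell is
guaranteed to be the nearest cell, making encode→decode an exact
inversion.

**Location refinement.** Cells within a radius (default 2σ, desk configs
1.5 cells) of a keypoint store the pixel offset `(x − c·stride,
y − r·stride)`; a mask limits the loss to those cells, since offsets far
from a peak are meaningless. When two instances' supports overlap on one
channel, the nearer instance owns the cell. Inside the training loss the
offsets are divided by the stride (so the head regresses values of order
1); decoding multiplies back (`adpt.decode.heads_to_px`).

**LRSS.** Every skeleton edge with both endpoints visible is rasterized
at head resolution as a thick segment (cells within `thickness/2` of the
segment, default thickness 2 cells; the rasterization criterion is
distance from cell center to the segment). Cells get the instance
identity (identity-aware mode) or 1; background is 0, so an
n-identity task uses n + 1 segmentation channels. Only limbs are painted
— the body interior is not filled; the segmentation is deliberately
coarse and doubles as an identity classifier by per-channel pixel-mass
voting. On overlap the first-listed instance keeps the cell, matching
the mix-up composite's animal-1 precedence.

**BAF.** On each cell of an instance's LRSS footprint the map stores
`p − center` in grid units (center = the skeleton's designated center
keypoint, the back for the default rodent skeleton); `(0, 0)` off-body.
Inverting the field (`p − BAF(p)`) reproduces the instance center
exactly, which is what groups body pixels by instance at decode time. An
instance whose center keypoint is invisible contributes nothing and is
counted in a diagnostics tally.

## Network

A shared convolutional backbone produces 1/4-scale features; three
branches then compute 1/4, 1/8 and 1/16-scale features. The 1/16 branch
is flattened to tokens, given learned 2-D positional embeddings and
passed through a transformer encoder — the global-context pathway that
underwrites the anti-drift behavior — then upsampled back to 1/8 by a
transposed convolution (kernel = stride = 2). The 1/4 branch reaches 1/8
via a stride-2 convolution. The three 1/8 feature maps are concatenated
(skip connections) and fused by a 3×3 convolution feeding four 1×1 heads:
K heatmap channels, 2K locref channels, n_identities + 1 LRSS channels,
2 BAF channels. Heatmap/locref/BAF heads are linear; LRSS is trained
with softmax cross-entropy. Inputs not divisible by 16 are zero-padded
(the padding is recorded, never an error).

Backbone presets:

- `tiny` (default): 5×5/2 + 3×3/2 conv stem → 32 channels at 1/4 scale.
  Small enough that training runs on one CPU in minutes while keeping the
  full three-branch + transformer geometry.
- `resnet`: 7×7/2 stem, 3×3/2 max-pool, and one three-block bottleneck
  stage (256 channels) — the first stages of a 50-layer residual network.
  It is built without batch normalization (the autodiff core intentionally
  has none; all trained paths in this package use `tiny`), and from random
  initialization: no pretrained weights are downloaded.

Transformer defaults: 2 encoder layers, 4 heads, embed dim 48, MLP ratio
2, learned positional embeddings on a 4×4 base grid bilinearly resized
(as a fixed linear map, so gradients flow) to the actual token grid.
These sizes are our choice for CPU-scale work; the architecture accepts
any via `ModelSpec`. Ablation flags `with_transformer=False` /
`with_lrss=False` remove a pathway without changing any remaining head
shape.

The whole network runs on `adpt.nn`, a reverse-mode tape over numpy
arrays. Convolution is im2col + matmul; transposed convolution requires
kernel = stride (non-overlapping upsampling); softmax, layer norm,
attention and the losses have fused hand-written backward passes, each
verified against central finite differences in the test suite.

## Training protocol

AdamW (β = 0.9/0.999, weight decay 1e-4, decay skipped for biases, norm
parameters and positional embeddings). Learning rate: linear warm-up
1e-5 → 1e-3 over the warm-up epochs, then cosine decay back to 1e-5.
Defaults: 190 epochs, 10 warm-up epochs, batch 8; identity/social
protocols use 300 epochs with a fixed iteration count per epoch (250 and
50 respectively) and monitor the training loss, while single-animal
training monitors a validation split (5% by default). Early stopping
after 30 epochs without improvement; the best-monitored-loss weights are
restored and checkpointed (npz weights + JSON sidecar with the model
spec, config and skeleton). The loss is
`w_hm·RMSE(heatmaps) + w_lr·RMSE(locref, masked) + w_seg·CE(lrss) +
w_baf·RMSE(baf)`, weights defaulting to 1 (desk configs double the
locref weight, the precision bottleneck at stride 8). RMSE is the root
of the per-head batch MSE; an MSE toggle exists since the two differ
only by gradient scale. A non-finite loss aborts with the offending
epoch/iteration; an empty dataset is a hard error.

Augmentation is a single similarity transform per frame (image and
keypoints move together; keypoints pushed outside become invisible).
Three parameter sets: `identity_task` (rotation ±30°, translation
x ∈ [−100, 100], y ∈ [−30, 15] px, scale 0.9–1.1), `social_task`
(translation only, same ranges) and `default`. The default ranges
(rotation ±25°, scale 0.9–1.1, translation ±20 px) are our choice of
mild general-purpose ranges in the spirit of the common keypoint-tool
defaults; the desk-scale protocol widens rotation to ±180° (synthetic
animals have uniform heading) and narrows translation to ±8 px (64-px
frames). When training is given raw labeled frames, they are
re-augmented and re-encoded every epoch.

## Decoding and identity

**Single animal.** Per channel: global argmax cell, coordinate
`cell·stride + locref`, rescaled by 1/global_scale; confidence is the
heatmap value clipped to [0, 1] (not renormalized). `detected` means
confidence strictly above the cutoff (default 0.2); an all-zero channel
is flagged invalid. Whole-frame identity is the argmax over identity
channels of the LRSS pixel sums; exact ties go to the lowest label, and
all-zero identity mass returns "unknown".

**Social (bottom-up + top-down).** Bottom-up: each body pixel p (LRSS
label ≠ 0) computes its center estimate `ĉ = p − BAF(p)`, rounded to the
nearest cell (clamped to the map and counted if outside); its identity is
the LRSS label at ĉ, falling back to the majority non-background label
within radius ρ of ĉ. Top-down: per heatmap channel, up to n_identities
non-maximum-suppressed peaks above the cutoff (NMS radius default 5
cells; desk configs 2) take the majority identity within radius ρ
(default 3 cells; desk configs 1) of the identity map; per (keypoint,
identity) only the highest-confidence peak survives (first in scan order
on an exact tie, with a warning). Peaks whose window is all background
are excluded and counted.

**Temporal identity correction.** The underlying procedure is a
motion-continuity pass, isolated behind one function so alternatives can
be swapped in: frame by frame, instances are optimally assigned
(Hungarian, scipy) to the previous frame's instances by summed center
displacement; when the raw identity labels contradict the assignment and
linking by raw labels would cost more than a hysteresis margin (default
10 px) of extra displacement, the motion-propagated labels win. A
sliding-window majority vote (default 15 frames) then removes isolated
flips. The pass changes identity labels only — never coordinates or
confidences — and is idempotent.

## Mix-up synthesis

Given two single-animal frames and a background of identical geometry:
animal 1 = pixels where the channel-max absolute difference from the
background is ≥ δ (inclusive); animal 2 = same test on frame 2, excluding
animal 1's pixels; everything else is background. The difference metric
(channel-max of absolute differences against a scalar δ, default 20 on
8-bit intensities) is our reading of the bare frame-minus-background
subtraction; δ is configurable since no canonical value exists. The
composite is a hard mosaic — every pixel comes verbatim from exactly one
source, no alpha blending or feathering — which keeps annotations exact
at the cost of photorealism (boundary artifacts are a known realism
limitation of this family of composites). Merged annotations: animal 1
keeps identity 1, animal 2 becomes identity 2, and animal-2 keypoints
that land inside animal 1's foreground are marked occluded (v = 0) — our
addition, since supervising occluded merged keypoints any other way
would teach the network to hallucinate. Generated datasets are
deterministic in the seed, and their identity-aware targets use exactly
labels {0, 1, 2} (three LRSS channels downstream).

## Evaluation metrics

- `drift@α` (per keypoint): fraction of frames whose Euclidean
  displacement from the previous frame exceeds α (defaults 50 px mouse,
  30 px monkey). The indicator direction as conventionally printed
  (`≤ α`) would count the *stable* frames; we count `> α` as drift —
  anything else contradicts "drift percentage" semantics — and expose a
  `count_stable` flag to flip. Distance is Euclidean, compared to α in
  pixels (α is a distance threshold, not a squared one).
- `miss`: fraction of frames with confidence ≤ 0.2, inclusive.
- `change_rate@α`: same displacement test on per-identity center
  trajectories (α default 75 px), averaged over identities; absent frames
  yield no displacement.
- Normalization of both rates is 1/F as conventionally printed, although
  only F − 1 displacements exist; with the flag flipped the two fractions
  sum to (F − 1)/F.
- `PCK@τ`: fraction of visible keypoints with error ≤ τ·L (τ default
  0.15). The reference length L defaults to the square root of the
  ground-truth bounding-box area — the "normalized limb scale" is
  otherwise undefined — and is configurable per skeleton
  (`pck_reference: "edge:i-j"` uses a limb length).
- `OKS`: `Σ_vis exp(−d²/(2·area·(2s)²)) / Σ_vis` with s = 0.025 —
  implemented exactly as printed, including the `(2s)²` factor that
  differs from the COCO `s²` convention; a strict-COCO mode sits behind a
  flag. Zero visible keypoints is a hard error (zero denominator).
- `AP@α` uses strict `OKS > α` (a tie at the threshold does not count);
  `mAP` averages the ten thresholds 0.50–0.95 in steps of 0.05.
- `RMSE`: root-mean-square Euclidean error, with optional
  confidence-cutoff reporting modes (0.2 and 0.6 conventions supported).

Every metric is checked against an independent per-element brute-force
implementation on randomized inputs.

## Synthetic fixtures

Scenes render articulated 5-keypoint stick figures (nose, back = center,
tail root, two paws) as thick limbs plus an oriented elliptical body in a
per-animal texture (base color × striped modulation keyed by texture id
— a learnable stand-in for coat appearance), with a small
distinct-colored marker disk at each keypoint, on flat/gradient/checker
backgrounds. Everything is reproducible from (spec, seed). Defaults: a
64×64 arena for single animals; two-animal scenes use 96×96 with ≥ 40 px
center separation, and two-animal videos 160×160 with ≥ 100 px
separation maintained during the motion (steps that would violate it are
rejected) — sized so that instances stay separable at the 8-px head
resolution and an identity swap exceeds the 75-px change-rate threshold.
Videos move animals by a reflected random walk (they never leave the
frame) with slowly drifting heading. Failure modes are injected *post
hoc* on the ground-truth track, never rendered: a jump adds a persistent
offset to one keypoint from its event frame onward (so it registers as
exactly one drift event), a swap exchanges the two identity labels for
one frame; the event log carries exact expected values for metric tests.

What passing on these fixtures does and does not show: the keypoint
markers make localization locally decodable and the textures make
identity learnable, so success demonstrates that the encoding, network,
decoding, identity and metric machinery are correct and that the
training protocol can drive the full pipeline to high accuracy — not
that the tiny network would track real, marker-less, deformable,
occlusion-heavy animals; that requires the full-size backbone and real
labeled data.

## Standard desk-scale experiment

`adpt.experiments` fixes the package's reference CPU experiment: 128
synthetic 64×64 training frames (plus 8 validation frames from a
disjoint seed stream), the tiny backbone, σ = 1 cell, locref radius 1.5
cells, locref weight 2, 80 epochs (5 warm-up) at batch 8 with per-epoch
augmentation, early stopping patience 30. Evaluation: PCK@0.15 on 32
held-out frames, drift at α = 16 px (≈ the bounding-box scale of these
scenes scaled from the 50-px mouse default) over a 200-frame video,
identity decoding from exact oracle head maps over 100 two-animal
scenes, and swap correction on a 100-frame pair video. These problem
sizes are the package's standard quick-verification experiment;
`scripts/acceptance.py` reruns all of it from scratch.

## Known limitations

- The transposed convolution requires kernel = stride; overlapping
  deconvolutions are not implemented.
- The `resnet` preset lacks batch normalization and pretrained weights,
  so it is a geometry/capacity preset rather than a drop-in for
  ImageNet-initialized backbones.
- Mix-up composites have hard boundaries; no photometric harmonization.
- Social decoding caps peaks per channel at the number of identities; a
  confidence-adaptive count is not implemented.
- The temporal identity pass assumes animals rarely teleport between
  frames; extremely fast crossings inside one frame interval can defeat
  the hysteresis rule.
- Video containers are read as image sequences (or anything
  `imageio` can open); no dedicated video I/O backend is bundled.
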