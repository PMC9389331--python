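# Methods

## Problem and model

The package detects roughly circular objects (greenhouse tomatoes are the
motivating case) in RGB images with an anchor-free, keypoint-based
detector.  An object is a *bounding circle* `(cx, cy, r)` rather than a
box: one fewer degree of freedom, rotation invariant, and a better shape
prior for round fruit.

The network maps an image `I ∈ R^{W×H×3}` to three maps on a stride-`K`
grid (`K = 4`):

- a per-class keypoint heatmap `Ŷ ∈ (0,1)^{C×H/K×W/K}` (sigmoid output),
- a class-agnostic 2-channel sub-cell offset map,
- a size map (1-channel radius for the circle head; 2-channel
  width/height for the box-head ablation).

Ground truth is encoded by splatting, for each object center `p`, an
unnormalized Gaussian around the discretized cell `p̃ = floor(p/K)` with
standard deviation `σ_p` from the rule below; overlapping Gaussians
combine by element-wise max so the heatmap stays in `[0,1]`.  The offset
target `p/K − p̃` restores what discretization discarded; the radius
target is `r/K` (all three heads share the output-grid coordinate scale,
and decoding multiplies back by `K`).  Because the stride is a power of
two, `p/K` and its integer/fractional split are exact in floating point,
and the encode→decode round trip on perfect maps recovers centers and
radii bit-exactly; the round-trip test relies on that.

Decoding finds cells that are greater than or equal to all of their
8-connected neighbors (plateau ties are all retained; border cells
compare only against existing neighbors), keeps the top `N ≤ 100` by
score, drops those under a confidence floor, and reads center and radius
off the offset and size maps.  A greedy circle-IOU NMS is available but
off by default — the keypoint formulation produces one peak per object.

## Circle IOU

For circles with radii `r1, r2` at center distance `d`, the intersection
on the lens regime `|r1−r2| ≤ d ≤ r1+r2` is the sum of two circular
segments with half-aperture angles

    α = arccos((r1² + d² − r2²) / (2 r1 d)),  β likewise with r1 ↔ r2,

giving `A∩ = α r1² + β r2² − ½ r1² sin 2α − ½ r2² sin 2β` and
`IOU = A∩ / (π r1² + π r2² − A∩)`.  Outside the lens regime the value is
extended by continuity: 0 for disjoint circles, `(min r / max r)²` for
containment.  Numerical choices: arccos arguments are clamped to
`[−1, 1]` (tangency configurations otherwise drift outside the domain and
produce NaN), and the operand pair is put in a canonical order before
evaluation so `ciou(a,b) == ciou(b,a)` holds exactly, not just to
rounding.  The aperture angles are named `aperture_a/aperture_b` in code;
the symbols α, β are reserved for the focal-loss exponents.

## Gaussian radius rule

The kernel width is not standardized in the keypoint-detection
literature, so the package adopts the IOU-derived convention of the
corner/center-point lineage, translated from box IOU to circle IOU: the
*Gaussian radius* is the largest displacement of a circle of radius `r/K`
against its own copy that keeps circle-IOU ≥ 0.7.  For equal circles the
IOU depends only on `d/r`, so this is `coeff · r/K` with a universal
coefficient (~0.3919) found once by bisection.  Then
`σ_p = max(gaussian_radius, 2)/3`, i.e. a floor of 2/3 output cell so
even tiny objects get a few soft-negative cells.  The splat window is
truncated at 3σ (omitted mass < 1.2% of the peripheral values, and the
`Y = 1` cells are unaffected).

Cell collisions (two centers in one output cell) keep the larger radius
and log a warning; the collision count is visible as the difference
between object count and keypoint-mask sum.

## Losses

With `N` keypoints per image (divisor 1 when an image has none, so empty
images cannot produce NaN):

- heatmap: penalty-reduced focal loss, exponents `α = 2`, `β = 4`;
  predictions clamped to `[1e-4, 1 − 1e-4]` before logs;
- offset and size: L1, gathered only at keypoint cells;
- total: `L_det = L_hm + λ_off·L_off + λ_r·L_r`, `λ_off = 1`, `λ_r = 0.1`.

The loss functions run in float64 when given numpy arrays (the oracle
tests compare them to per-cell loops at 1e-10) and in float32 through the
training tape.

## Network

The backbone follows the deep-layer-aggregation pattern at reduced and
full scale:

- `tiny`: stages of 8/16/32/64 channels at strides 1/2/4/8, one residual
  block per stage (~174k parameters);
- `dla34_cbam`: 16/32/64/128/256/512 at strides 1..32, two residual
  blocks per stage fused by a 1×1 aggregation node (the tree-style
  within-stage merge).

A CBAM block — channel attention (shared two-layer bottleneck MLP over
average- and max-pooled descriptors, reduction 4 tiny / 16 full) followed
by spatial attention (7×7 conv over the channel-wise mean and max maps),
each a sigmoid gate multiplied onto the features — is applied to every
stage output.  Reading "replace the original layers with CBAM" literally
would remove the stage's convolutions, destroying feature extraction, so
the package inserts CBAM on each stage's output instead; `use_cbam=False`
removes the gates entirely, which is the attention ablation axis.
Deeper features are fused back to stride 4 by iterative
project→upsample→merge steps (nearest-neighbor ×2 upsampling, 3×3 merge
convolutions); deformable convolutions are deliberately not used.  Heads
are independent siblings (3×3 conv → ReLU → 1×1 conv); the heatmap head's
final bias starts at `−log(99)` so the initial foreground probability is
~0.01 and the focal loss does not saturate on the empty background early
in training.

Everything runs on a small reverse-mode autograd engine over numpy
(im2col convolutions lowered to BLAS matmuls); gradients of every op are
checked against central finite differences in the test suite.  All weight
initialization flows from one seed.

## Synthetic scenes

The generator emulates the structure of greenhouse imagery rather than
its appearance: shaded reddish discs (radial shading + specular
highlight, eccentricity ≤ 5% so fruits are only *roughly* circular) over
a textured green background with elliptical clutter blobs; leaf-shaped
occluders cut a chord across a fruit at the exact pixel quantile that
realizes a requested coverage fraction; fruit overlap is placed by
rejection sampling; illumination is uniform, a sunlight-style linear
gradient, or a dim "shading" multiplier; optional Gaussian blur stands in
for motion blur.  Occlusion is *measured* per fruit by pixel counting on
the final ownership map (later-drawn fruits count, exactly as leaves do)
and labeled slight (< 50% hidden) or severe (≥ 50%).  Defaults: 64×64
scenes, 1–4 fruits of radius 6–11 px, overlap probability 0.25, occluder
probability 0.35 with coverage 0.1–0.6, blur probability 0.2.  Every
scene is a pure function of its seed.

What passing tests on these scenes does **not** show: robustness to real
foliage texture, to color variation of unripe fruit, to camera noise, or
to the scale statistics of 512×512 greenhouse photographs.  The generator
validates the machinery (geometry, encoding, optimization, evaluation),
not field performance.

Annotations use a plain-text dialect (no format is standardized for
circle ground truth): first line the object count, then
`class_id cx cy r` per line, 0-based pixels with 2 decimals; detection
files append a 4-decimal score.  Round trips are lossless at that
precision.

## Augmentation

Per original: horizontal flip; one scale-and-crop draw (factor uniform in
[0.75, 1.25], center crop/zero-pad, circles transformed by the same
similarity, circles whose centers leave the frame dropped); two
brightness draws, one darkening in [0.6, 1) and one brightening in
(1, 1.4] (pixels scaled and clipped); gray-world color balancing (each
channel scaled to the mean of the channel means; zero-mean channels left
alone with a warning); and one Gaussian blur (kernel 5) of a randomly
chosen derived image.  With the original included the multiplicity is 7,
reproducing the published expansion bookkeeping (725 → 5,075 with the
brightness category at 1,450).

## Training and evaluation

Full-scale defaults: 512×512 input, batch 8, initial rate 1.25e-4
divided by 10 at epochs 90 and 120 over 140 epochs.  The desk-scale
preset — the configuration this package is actually exercised at — is the
tiny network on 64×64 scenes, Adam at 3e-3 with the same step-decay shape
(drops at 70% and 90% of the run), batch 8, ≤ 30 epochs, gradient-norm
clip 5, 10% of the training images held out (seeded) for
best-checkpoint-by-validation-AP selection.  The higher rate is
appropriate for a 174k-parameter network trained from scratch; the
published full-scale schedule is kept as the default for the full
preset.  Problem sizes used
throughout the tests and the acceptance script: 200 training and 50 test
scenes.

Evaluation matches greedily: detections in descending confidence claim
the unclaimed ground truth of highest circle-IOU ≥ 0.5 (the matching
threshold is exposed; 0.5 is the community default since no value is
published for this protocol).  Summary precision/recall/F1 and the
stratified tables are computed at confidence 0.6, the published operating
point; the PR curve and the all-point interpolated AP pool detections
down to a lower floor (0.05) because a curve truncated at the reporting
threshold cannot reach its full recall range.  Stratified tables divide
correct and missed rates by the stratum's ground-truth count and the
false rate by the stratum's detection count (TP + FP) — the convention
recoverable from the published rate tables.  False positives inherit the
image's lighting label and the occlusion label of the most-overlapping
ground truth ("slight" when the image has none); the unoccluded map to
"slight" in the two-level scheme.  Rounding is half-away-from-zero to two
decimals.

For the box-head ablation the size head predicts (w, h) = (2r, 2r)
targets and detections are scored as their equivalent circles
(r = (w + h)/4), so both head types flow through one evaluation path.

## Known limitations

- The backbone honors the aggregation pattern and stage counts, not the
  original tree topology down to block internals; no pretrained weights.
- Training is CPU-scale by design; the full 512×512/140-epoch schedule is
  configured but not exercised by the tests.
- The synthetic scenes are far easier than real imagery; absolute metric
  values on them say nothing about field accuracy.
- Single-class only in practice (C is configurable but the generator
  emits one class).
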