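# tomatodet

Anchor-free detection of roughly circular objects — greenhouse tomatoes
being the motivating crop — for harvesting-robot vision systems and
anyone benchmarking keypoint-based detectors on round targets.

Instead of a bounding box, an object is a **bounding circle**: its center
is a keypoint on a class heatmap `Ŷ ∈ [0,1]^{W/K × H/K × C}`, and its
radius is regressed at that keypoint.  Ground-truth centers are splatted
as Gaussians `Y_{xyc} = exp(−((x−p̃_x)² + (y−p̃_y)²)/2σ_p²)`; a sub-cell
offset head cancels the stride-`K` discretization, so decoding a peak
gives `p̂ = (x̂ + Δx̂, ŷ + Δŷ)·K` and `r̂ = R̂_{x̂ŷ}·K`.  Overlap between
circles is scored by a closed-form **circle IOU** built from circular
segments with half-aperture angles `α = arccos((r1²+d²−r2²)/2r1d)` (and
symmetrically `β`), extended by continuity to disjoint and contained
pairs.  Training minimizes

    L_det = L_hm + λ_off·L_off + λ_r·L_r,   λ_off = 1, λ_r = 0.1,

where `L_hm` is a penalty-reduced focal loss (α = 2, β = 4) and the other
two are keypoint-masked L1 terms.  The backbone is a deep-layer
aggregation network with a CBAM attention gate (channel then spatial) on
every stage output; a `tiny` preset (~174k parameters) trains on a CPU in
minutes.  Because no public dataset exists for this task, a seeded
synthetic scene generator renders annotated fruits with controllable
occlusion, overlap, illumination and blur.  The numeric stack (including
a small reverse-mode autograd engine) is pure numpy/scipy.

## Worked example

```sh
tomatodet synth  --out-dir data --n-train 200 --n-test 50 --seed 0
tomatodet train  --data-dir data --out-dir run --epochs 30 --seed 0
tomatodet detect --checkpoint run/best.npz --image-dir data/test/images \
                 --out-dir dets --score-threshold 0.05
tomatodet eval   --det-dir dets --gt-dir data/test/labels \
                 --manifest data/manifest.csv --report report.json
```

The eval step prints a report like (abridged; numbers from this exact
seeded run):

```json
{
 "tp": 108, "fp": 1, "fn": 17,
 "precision_pct": 99.08, "recall_pct": 86.4, "f1_pct": 92.31,
 "ap_pct": 98.56,
 "strata": {
  "lighting":  {"shading":  {"correct_rate": 90.48, ...},
                "sunlight": {"correct_rate": 82.26, ...}},
  "occlusion": {"severe":   {"correct_rate": 36.84, ...},
                "slight":   {"correct_rate": 95.28, ...}}
 }
}
```

Read it as: at the confidence-0.6 operating point the detector finds 108
of 125 held-out synthetic fruits with one false alarm; sweeping all
confidences gives an interpolated average precision of 98.6%.  The
stratified tables show the expected structure — severely occluded fruits
(≥ 50% hidden) are missed far more often than slightly occluded ones,
while the two lighting conditions score broadly similarly.  The same pipeline is
available as library calls (`tomatodet.harness.train`, `detect`,
`evaluate_cmd`).

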