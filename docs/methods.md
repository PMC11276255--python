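# Methods

## The problem

Immunohistochemistry sections (Ki-67-style nuclear staining) contain two
classes of nuclei — stained and unstained — whose ratio, the *unstained rate*
`unstained / total`, is the quantity of interest for downstream tissue-quality
assessment. Counting by eye is slow and operator-dependent. `dcrnet` frames the
task as two-stage object detection: localise every nucleus with a bounding
box, classify it as stained or unstained, and report per-class counts and the
unstained rate.

## The detector

The pipeline is a Faster-R-CNN-style two-stage detector. An input image is
resampled to a fixed canonical size (1800×1200 by default; desk-scale
configurations run at the native field size), passed through the backbone and
a feature-pyramid network (FPN) giving maps at strides 4/8/16/32, scored
densely by a region-proposal network (RPN), and the surviving proposals are
RoI-aligned to 7×7 and classified as stained / unstained / background with a
class-agnostic box refinement.

### The DCRNet backbone

Three changes distinguish the backbone from a plain residual network:

1. **Aggregated residual blocks.** The bottleneck transform is split into
   `cardinality` parallel low-width paths — implemented as a grouped 3×3
   convolution between 1×1 reduce/expand layers, which is algebraically
   identical to summing the paths (verified in the tests by expanding the
   groups explicitly). At the reference setting — 256 channels, cardinality
   64, path width 2 — the block has 67,840 convolution weights against 69,632
   for the plain 64-wide bottleneck, with multiply–adds within 3%: more paths,
   slightly fewer parameters, same cost. The per-path width is not fixed by
   the architecture family; width 2 is the unique small value that makes the
   block simultaneously fewer-parameter and complexity-matched, so it is the
   default and it is configurable.
2. **Information-preserving down-sampling.** Stage transitions use a 2×2
   average pool (stride 2) followed by a stride-1 1×1 convolution. A strided
   1×1 convolution reads one pixel per 2×2 block and provably ignores 75% of
   grid positions (the tests perturb every input pixel of an 8×8 map
   exhaustively); the average-pool form gives every position a nonzero path to
   the output, which matters when a nucleus is only a few pixels wide.
3. **Deformable 3×3 convolutions** in the last two stages (configurable).
   Each kernel tap `Pn` samples at `P0 + Pn + ΔPn`, where the per-location
   fractional displacements `ΔPn` come from a parallel zero-initialised
   convolution, so training starts exactly in the standard-convolution regime.
   Fractional positions are bilinearly interpolated; samples outside the map
   contribute zero. Offsets receive exact gradients (checked against finite
   differences to 1e-3), letting the receptive field stretch along
   spindle- and bar-shaped deformed cells.

Batch normalisation follows every convolution; activations are rectified
linear. Stage depths default to (3, 4, 23, 3) — the 101-layer residual layout
— and scale down to (1, 1, 1, 1) for desk-scale work.

### Numerical core

The network runs on a small reverse-mode automatic-differentiation engine
over numpy arrays written for this package (`dcrnet.autograd`). Convolution
is im2col + batched matmul with a zero-copy fast path for 1×1 kernels;
deformable convolution and RoI align share a vectorised bilinear
gather/scatter. Every operator's gradient is validated by central finite
differences in the test suite. Computation is float32; batch-norm running
statistics are float64.

## Training

The published curriculum is preserved and scalable: a warm-up phase on
low-resolution tiles (640×480 or smaller) for 30 epochs, then the complete
training set for 270 epochs, batch size 4, loss recorded every 5 iterations,
SGD with momentum 0.9 and base learning rate 0.02·(batch/16). A single scale
factor shrinks the epoch counts for desk-scale runs. Training aborts on a
non-finite loss, saving the last finite state. Anchors, NMS thresholds,
proposal counts and RoI sampling use standard two-stage conventions (scales
{32,64,128,256} × ratios {0.5,1,2}, RPN IoU 0.7/0.3, 1000/300 proposals,
64 RoIs at 25% positive fraction); all are configuration, not constants.

### Desk-scale configuration

The desk-scale preset (used by the tests and the reproduction script) is a
miniature of the same architecture: stem width 8, stage depths (1,1,1,1),
stage widths (24,32,48,64), cardinality 8 × width 2, FPN width 32, anchors
bracketing 14–176 px, native 320×240 input. It trains with batch 2, learning
rate 0.01, 50 warm-up iterations and a 300-iteration budget — about two
minutes on one CPU core. The ablation baseline is the same miniature with
cardinality 1, strided down-sampling and no deformable convolutions.

## Synthetic fields

The generator (`dcrnet.synth`) emulates the statistical structure of stained
sections rather than their appearance: anti-aliased elliptical nuclei in two
colour classes (blue-ish = stained, brown-ish = unstained by default; the
mapping is configurable because source imagery is inconsistent about it),
per-cell colour jitter, a light low-frequency textured background, Gaussian
sensor noise (σ = 3/255), a configurable fraction of spindle/bar-deformed
cells (axis ratio ≥ 3), adherent pairs overlapping 10–40% of the smaller
cell's area (solved on effective-radius circles by bisection), and near-black
multi-lobed distractor blobs that are deliberately left out of the
annotations as false-positive bait. Identical specifications (including the
seed) render bit-identical fields.

Default desk-scale conditions: 320×240 px, 15 nuclei of radius 8–16 px,
stained fraction 0.19 (mirroring the reported rate's magnitude), 10%
deformed, 20% adherent, 2 distractors. The learning experiments use 60
training and 20 held-out fields.

What the generator does *not* model: nuclear texture, chromatin structure,
uneven illumination, section folds, out-of-focus blur, dense tissue context.
Passing the desk-scale tests therefore demonstrates that the implementation
is correct and trainable end to end — that proposals localise high-contrast
nuclei, the head separates the colour classes, counts flow through — not
that this miniature would transfer to real histology; that claim requires
real data and full-scale training, which are out of scope here.

## Evaluation

COCO-style average precision: greedy confidence-ordered matching per image
(each ground truth matched at most once), 101-point interpolation of the
precision–recall curve, mean over IoU thresholds 0.50:0.05:0.95 and over the
two classes, reported ×100. Size strata follow the 32²/96² box-area
thresholds; boundary areas belong to the medium band, ground truths outside
a stratum are ignored (not false-positive fodder), as are unmatched
detections outside it. With no ground truth at all, AP is reported as
undefined — never silently zero. The implementation is checked to 1e-6
against a brute-force transcription of the definition on small instances.
The 101-point integrator is a deliberate choice; all-point interpolation
would differ in the third decimal on small sets.

Counting applies a confidence threshold (default 0.5, exposed in
configuration because low-confidence unspecific stains cannot be filtered by
thresholding alone) and reports stained/unstained/total and the unstained
rate, with full precision internally and printed rounding only in reports.

## Dataset engineering choices

* VOC XML uses 1-based inclusive pixel coordinates; in memory every box is
  0-based half-open. The two converters in `dcrnet.data` are the only place
  the mapping occurs.
* Tiling requires exact divisibility and covers the image without overlap.
  Boxes straddling tile borders are clipped; a clipped box is dropped when
  its visible area falls below `min_visibility` (default 0.25) of the
  original — slivers teach nothing — and `min_visibility=0` keeps every
  positive-area intersection, which is the setting under which tiling
  provably conserves all boxes.
* The 6:3:1 split allocates `round(0.6n)` / `floor(0.3n)` / remainder per
  resolution group: this is the allocation consistent with the published
  per-group counts (225 → 135/67/23), which a naive `round` of 0.3n would
  not reproduce.
* The canonical resize maps to a fixed 1800×1200 (w×h) without preserving
  aspect ratio; boxes scale per axis and round half-up.

## Known limitations

* No GPU path; full-scale (depths 3,4,23,3, cardinality 64) training is out
  of reach on a CPU. A weight-loading hook accepts externally pre-trained
  backbone checkpoints.
* Deformable convolution is the v1 form (offsets only, no modulation mask).
* Class-agnostic box refinement in the head; per-class regression would add
  parameters without benefit at two classes.
* Adherent spindle-shaped cells with end-to-end adhesion remain the hard
  case, at desk scale exactly as at full scale.
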