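# Methods

## Problem and approach

Organoids are grown suspended in hydrogel droplets and monitored by
low-magnification brightfield imaging. A single droplet image (typically
1500 × 1125 px, 8-bit) can hold tens to hundreds of organoids and
suffers from occlusion, defocus, heterogeneous sizes, uneven lighting
and extreme density variation, which defeats classical global
segmentation. This package implements the tiled-detection strategy for
such images: cover the image with overlapping square windows, run an
object detector per window, discard detections that graze interior
window edges, map the survivors to global coordinates, de-duplicate
across windows, and convert each final bounding box into physical size
measurements.

The detector is pluggable. The package ships a classical reference
detector so the whole chain runs and is testable at desk scale; a
trained neural network can drive the same pipeline through the
subprocess adapter (patch in as PNG, detections out as CSV) without
adding any ML runtime to this package.

## Coordinate and box conventions

All boxes are axis-aligned, 0-based, origin at the image top-left, and
half-open: a box covers pixel columns `[xmin, xmax)` and rows
`[ymin, ymax)`. Half-open boxes make widths exactly `xmax − xmin` and
areas additive, and IoU is computed on these areas. The annotation CSV
schema (`filename,width,height,class,xmin,ymin,xmax,ymax`) is read
under the same convention; the schema itself fixes only the origin, so
the half-open reading is a documented choice of this package, not a
property of the format. A reader flag also accepts the raw
crowdsourcing dialect that stores box width/height instead of max
corners.

## Tiling

`plan_tile_grid(width, height, patch_size, overlap)` computes, per
axis, the smallest window count `n` with
`(n − 1)·stride + patch_size ≥ extent` (`stride = patch_size −
overlap`), pads the image at the bottom and right with black (zero)
pixels to exactly `(n − 1)·stride + patch_size`, and enumerates window
origins row-major. Defaults are a 450-px window with 50% overlap
(fractional overlaps are converted by rounding down). With 50% overlap,
any box smaller than the stride is fully interior to at least one
window, which is what makes edge filtering lossless (next section).

## Edge filtering and cross-window aggregation

Detectors are unreliable on objects cut by their window edge, so any
detection whose box comes within `edge_margin` px (default 2) of a
window side is dropped — unless that side lies on the original image
border (or beyond it, in the padding strip), where no overlapping
neighbour exists and dropping would permanently lose perimeter
organoids. The 2-px default tolerates detectors that clamp boxes to
the window frame.

Surviving boxes are translated by their window origin and clipped to
the original (unpadded) frame; boxes wholly inside the padding strip
vanish. Duplicates across overlapping windows are resolved by greedy
non-maximum suppression at IoU 0.5 (default): detections are visited
by descending score, ties broken lexicographically on box coordinates,
and one is kept iff it overlaps every kept detection below the
threshold. NMS was chosen over box averaging/fusion as the
conventional, idempotent resolution; the threshold is configurable.

Correctness of the plumbing is established with an oracle detector
that returns known ground-truth boxes clipped per tile: for scenes
whose organoids fit within `stride − 2·margin`, the pipeline output
equals the ground truth box-for-box.

## Reference detector

A difference-of-Gaussians blob detector acting on the inverted,
[0, 1]-normalized grayscale patch (organoids are dark on bright
background, so inversion makes blob response positive):

1. band-pass response `G(σ_fine) − G(σ_coarse)` of the inverted patch;
2. binarize (Otsu by default, or a fixed fraction of the peak
   response); Otsu is only trusted when it lands above zero response,
   which rejects blank patches where it would split noise;
3. morphological closing (disk radius 3) and hole filling, so the dark
   rim plus light lumen becomes one solid component;
4. connected components; discard area < `min_area`;
5. focus gate: mean image-gradient magnitude along the component
   boundary must reach `focus_threshold`, rejecting heavily defocused
   bodies whose edges have washed out — mirroring the annotation
   convention that only in-focus organoids are boxed;
6. tight bounding box per surviving component, scored by the
   component's mean band-pass response normalized by the patch peak,
   and floored at `score_floor`.

Defaults (σ_fine 2 px, σ_coarse 15 px, Otsu, min_area 150 px²,
focus_threshold 0.015 intensity/px, score_floor 0.2) are matched to
the synthetic generator's default organoid radii (15–60 px per
semi-axis). They are fixture parameters: nothing here is a claim about
real cultures, where a trained detector through the adapter is the
intended backend. Known limitation: large organoids whose lumen
dominates the filled component get low normalized-contrast scores and
can fall under the score floor; on clean synthetic scenes the detector
recovers ≈ 93% of organoids rather than all of them.

## Morphometry

Each final box is assumed to contain an inscribed ellipse: semi-axes
are half the box sides. With pixel scale `s` (µm/px, user-supplied;
scale-bar OCR is out of scope), a `w × h` px box reports
`major = max(w, h)·s`, `minor = min(w, h)·s`, and projected area
`π/4·w·h·s²`. The measurement type enforces the area identity at
construction. Per-image output is one CSV
(`filename,xmin,ymin,xmax,ymax,score,major_axis_um,minor_axis_um,area_um2`),
rows ordered by descending score then box coordinates for
deterministic output, plus a labeled overlay PNG written beside the
source image.

## Annotation consensus

The crowdsourcing workflow has each patch boxed by two workers, with a
third worker added when agreement falls below 80%, and a consensus box
retained only at ≥ 70% worker support. The platform's internal
formulas are not public, so this module implements a documented
reading:

- agreement between two workers = `2·|matches| / (|a| + |b|)` over a
  greedy IoU matching at 0.7 (Dice-style; 1.0 when both sets are
  empty);
- escalation iff agreement < 0.8, strictly;
- consensus clusters are formed by constrained agglomerative merging:
  cross-worker box pairs with IoU ≥ 0.7 are visited in descending IoU
  order (ties broken on box coordinates, making the result independent
  of worker order) and merge when their clusters share no worker;
  cluster support = contributing workers / all workers; clusters at
  ≥ 0.7 support yield the coordinate-wise mean box, rounded to
  integers.

A direct consequence: with three workers, 2-of-3 support (0.667) falls
below 0.7 and the box is dropped. That is the strict reading of the
70%-of-all-workers rule; a mean-IoU interpretation would behave
differently, and the choice is surfaced here deliberately.

## Evaluation metric

The per-image score is the fraction of ground-truth boxes found by the
predictions, where "found" means a greedy one-to-one match at
IoU ≥ 0.7; duplicate predictions of one organoid count once, and
false positives do not lower the score (the metric is a recall under
the standard taxonomy). The dataset score is the arithmetic mean over
images with at least one ground-truth box; images without ground truth
are excluded because their fraction is undefined. The conventional
VOC/COCO average precision is deliberately not implemented — this
package reproduces the recovery metric as defined, and tests verify
greedy matching equals optimal assignment on instances up to 5 boxes a
side.

## Synthetic scenes

The generator renders each organoid as a rotated ellipse whose
transmittance profile has a bright-ish lumen (0.78) and a dark rim
(dipping to 0.38, triangular across the outer 22% of the radius) on a
bright background (0.88), multiplied into the canvas so overlapping
organoids darken each other as occluding bodies do. A configurable
fraction of organoids is defocused by per-organoid Gaussian blur of
their transmittance layer; a linear illumination field (peak-to-peak
ratio configurable) and Gaussian pixel noise are applied before 8-bit
quantization. All randomness flows from one seeded generator in a
fixed draw order, so scenes are exactly reproducible.

Ground truth records, per organoid, the tight box of the rendered
mask *before* blurring, an in-focus flag, and the true semi-axes.
Defaults emulate the study conditions: 1500 × 1125 px frames,
semi-axes 15–60 px, noise σ = 2 intensity units. Non-overlapping
placement uses rejection sampling (1000 retries per organoid).

What the generator does not emulate: crypt/budding (non-spherical)
morphologies, textured lumens, debris, vignetting beyond a linear
ramp, or the droplet boundary. Passing tests therefore demonstrate
that the pipeline plumbing and the reference detector behave correctly
on idealized brightfield-like scenes — they say nothing about any
detector's accuracy on real cultures.

## Dataset bookkeeping

`patchify_for_annotation` cuts non-overlapping, grid-aligned patches
(300 and/or 450 px) from the top-left; partial strips at the bottom
and right are discarded — remainder handling is a dialect choice of
this package. `train_test_split` (default 10% test) splits at the
filename level so all boxes of one patch stay together; splitting by
box would leak patches across the split.

## Problem sizes in the test suite

Pipeline-level tests and the acceptance suite use 20 seeded
1500 × 1125 scenes per scenario (5–60 organoids for the oracle check,
25 for the reference-detector check), 1000 random box pairs for the
IoU oracle, and exhaustive 2-box (10,000) and 3-box (46,656) lattice
instances for the NMS oracle. On one CPU the full suite runs in a few
minutes.
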