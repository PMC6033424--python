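# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations behind `spinefind`, in the order the pipeline runs.

## Conventions

Coordinates are 0-based `(row, col)`, row 0 at the top, everywhere; label
files store the same convention (1-based sources must be converted at the
I/O boundary). Calibration is a single scalar in px/µm; µm↔px conversion is
exact multiplication/division by it. Intensities are min-max normalized per
image to [0, 1]; a constant image maps to zeros. Only one 2D plane of a
stack is processed (a plane index or a maximum-intensity projection can be
selected at load time). Foreground is 8-connected and background
4-connected throughout, so filling and perimeter logic never disagree about
diagonal contacts.

## Binarization

* Median filter: 3×3 by default (configurable), replicate padding.
* Global background threshold: Otsu's level reduced by 70 %
  (`applied = 0.3 × otsu`). The reduction is "by", not "to": the lowered
  threshold marks certain background so no dim tissue is lost. The mean of
  pixels strictly below it is subtracted; negatives clip to 0.
* Adaptive threshold: local first-order statistic = local mean over a
  window of `round(10 µm × scale)` px forced odd and clamped to the image,
  replicate padding, sensitivity factor 1.0 (configurable). Strict
  greater-than comparisons carry a 1e-12 guard so a numerically constant
  image cannot flip foreground on box-filter rounding noise.
* The reduced global threshold, shifted by the subtracted background level,
  also acts as a floor during binarization. Without it, min-max-normalized
  background noise sits just above its own near-zero local mean and the
  background speckles; with it, segmentation covers ≥ 95 % of the true tube
  and < 2 % of pure background on the synthetic fixtures. The floor can be
  disabled (`apply_global_floor=False`).
* Holes: 4-connected background components not touching the border with
  area strictly below 0.5 µm² × scale² are filled.

Because normalization precedes both thresholds, the mask is invariant to
affine rescaling of the raw intensities.

## Backbone

`M = round(2 µm × scale)` (ties half up) is the minimum branch length; the
border margin protecting endpoints during trimming is 1.5 µm (the same
margin used for label boxes; the choice is not critical and is
configurable).

* Thinning: Guo–Hall (`skimage.morphology.thin`) followed by a cleanup pass
  that deletes one topology-preserving pixel per residual 2×2 block
  (Zhang–Suen deletability first, an exact global component/hole-count
  check as fallback), guaranteeing the unit-thickness invariant.
* Loop removal: enclosed regions < 0.5 µm² are filled, then re-thinned.
* Isolated segments with p < M pixels are deleted (strict).
* Trimming: the nested peeling loop. For m = 1…M (inclusive), endpoints are
  peeled m times into a deleting template; a removed 8-connected segment of
  exactly m pixels kept growing every iteration, so it belongs to a longer
  structure and is restored; templates that stopped growing are complete
  short branches and stay deleted. "Restore exactly m" is the default
  (literal) reading; `restore="at_least"` is available. For peeling, an
  endpoint is a pixel whose foreground neighbors form a single contiguous
  arc of its 8-ring — this covers the ordinary one-neighbor endpoint and
  the final branch pixel resting against a line, which a strict
  one-neighbor rule would leave behind as a stub. For reporting,
  `endpoints()` keeps the standard one-neighbor definition.
* Kink smoothing: branch points of the untrimmed skeleton that survive on
  the trimmed backbone are dilated by a disk of radius `round(M/4)`;
  backbone pixels inside are deleted and each two-ended gap re-bridged with
  a Bresenham line (then re-thinned). Gaps with more or fewer than two
  attachment points, or repairs that would close a new loop, are rolled
  back.
* Components shorter than M pixels are dropped at the end, so every final
  component carries at least the minimum branch length.

A consequence worth knowing: a spine whose skeleton branch is *longer* than
M (stalk + head beyond ~2 µm at 15 px/µm) survives trimming and stays part
of the backbone — the minimum-branch-length rule cuts both ways. Such
spines stop being geodesic maxima and are not proposed as candidates.

## Surface smoothing

Stage order is fixed: majority (≥ 5 of the 9-cell neighborhood, center
included, zero-padded) → open, close, open with a 3×3 all-ones element
(erosion treats outside-image as foreground, dilation as background, so the
frame does not erode objects) → iterative removal of pixels with < 3
foreground 8-neighbors, to a fixed point → diagonal fill (for each 2×2
block holding exactly one diagonal foreground pair, the top-most then
left-most background pixel is set; repeated to stability) → thickening by
one pixel in raster order, where a pixel is skipped if it would bridge two
distinct components or if it is a one-pixel background region whose filling
would erase it. Components below 4 px are dropped afterwards.

Notes: the majority filter shaves convex 90° corners (4 < 5), and the
thickening grows every object by one pixel — the stack is a repair, not an
identity, even on clean masks. Smoothing can also pinch off one-pixel
interior holes; these stay as obstacles for the geodesic transform but are
not part of the spine-facing surface, so the perimeter trace runs on the
hole-filled outer boundary.

## Detached objects

Components without backbone pixels but within Euclidean distance M px of
the backbone are kept for reporting; farther ones are dropped. SNR = mean
intensity over the object ÷ mean over its bounding box minus the object
(box expanded by one pixel when degenerate; a zero-noise surround yields
the largest representable float). With more than two objects, the SNRs are
split by the globally optimal 1-D two-cluster partition (exhaustive split
over sorted values — deterministic, no Lloyd iterations, no seed); the
larger-mean cluster is the spine group; all-equal SNRs degenerate to one
spine cluster. With ≤ 2 objects nothing is clustered. All detached objects
are removed from the working mask regardless of their triage.

## Features

* Geodesic transform: 8-connected shortest path with quasi-Euclidean
  weights (1 axial, √2 diagonal) via `skimage.graph.MCP_Geometric`, scaled
  to µm. Unreachable or off-mask pixels carry an infinite sentinel.
* Perimeter trace: the outer boundary contour (Moore neighbor tracing,
  clockwise) of the component, cut at an RNG-chosen pixel; positions are
  cumulative quasi-Euclidean arc length from the cut. The trace is
  validated to be a simple closed curve — any duplicated pixel (spur,
  kink) or missed boundary pixel raises an error naming the offenders.
  Positions are exactly cut-invariant up to a cyclic shift.
* Candidates: strict local maxima of the dendrite-seeded geodesic values in
  circular trace order; plateaus yield their middle pixel (first of two for
  even lengths); no prominence threshold. Maxima within 1.5 µm of the image
  border are dropped at detection time, the same margin the labeling rules
  use, so training and inference see identical candidate sets.
* Spine backbone: traceback through the shared Dijkstra front seeded at the
  backbone (one front per image, one traceback per candidate); its
  recomputed arc length equals the geodesic map value at the origin to
  1e-9.
* PD/PS windows: values are linearly resampled at 100 evenly spaced arc
  positions spanning exactly ±2.5 µm around the origin, unwrapped
  circularly across the cut, then min-shifted to 0 (min after resampling,
  which guarantees min = 0 exactly). Perimeters shorter than the window
  fall back to the whole perimeter with a warning.
* IS: 20 linear interpolations of image intensity along the spine backbone
  ordered dendrite → tip, plus the backbone length in µm as value 221.
  Intensities come from the median-filtered normalized image by default
  (noise robustness); the raw normalized image is selectable. IS therefore
  scales with global intensity rescaling, while PD and PS are purely
  geometric.

## Labeling and splits

A 1×1 µm box is centered on each click. A box whose nearest *edge* lies
within 1.5 µm of any border is excluded (so the transition sits at a
box-edge distance of exactly 1.5 µm, i.e. click distance 2.0 µm); a box
overlapping a detached object is excluded as well. Candidate origins inside
an active box (boundary inclusive) are spine rows; candidates inside only
excluded boxes are dropped; everything else is non-spine. Splits are
60/20/20, seeded, candidate-level, stratified by class (stratification is a
choice — it stabilizes small-corpus metrics); an image-level split is
available behind a flag for leakage-sensitive use.

## Classifier

221 → 20 (tanh) → 2 (softmax), cross-entropy; inputs min-max normalized to
[−1, 1] with constants fit on the training split (constant features map to
0). Weights and biases initialize uniformly in [−1, 1] from the seeded
generator. Training is Møller's scaled conjugate gradient with σ = 5e-5 and
λ₀ = 5e-7, full batch; a restart along the gradient every N(weights)
iterations; stopping on max_iter (default 1000), gradient norm < 1e-6, or 6
consecutive validation-loss increases with best-validation weights
restored. Accepted steps never increase the training loss. Class imbalance
(≈ 1:4–5 on synthetic corpora) is left unweighted. Models serialize to a
single JSON container (architecture, weights, normalization, stop reason);
save → load → predict is bit-stable to 1e-12.

## Synthetic generator

Emulates single-plane two-photon images of GFP-filled dendrites at the
defaults: 128 px frame, 15 px/µm, tube radius 0.35 µm, 2–5 spines per image
(stalk 0.5–2.5 µm × 0.15 µm radius, head 0.2–0.5 µm, perpendicular to the
dendrite, tips kept ≥ 2.2 µm from the border so their label boxes stay
active), 2–5 shallow bumps (radius 0.15–0.30 µm, amplitude below the tube
radius) as the non-spine class, Gaussian PSF σ = 0.15 µm, background offset
0.08, and Gaussian noise with variance proportional to the mean
(gain 0.005) plus additive read noise (σ = 0.02) — the standard two-photon
noise shape. Spine anchors sit ≥ 1.2 µm apart along the dendrite and tips
≥ 1.6 µm apart so 1×1 µm boxes never cover two spines; placement honors
these hard constraints, so an image occasionally carries one spine fewer
than sampled (ground truth always records what was actually drawn).
Everything is deterministic given the seed; corpora fan one seed out to
per-image child seeds.

What the generator does *not* emulate: out-of-focus fluorescence from other
z-planes, dendrite branching, overlapping or occluded spines, motion/drift,
photobleaching, and realistic spine-shape diversity (mushroom vs. thin vs.
stubby). Passing tests on this data shows the pipeline recovers the
geometry it is specified to recover under calibrated noise — not
field-readiness on arbitrary microscopes.

## Problem sizes in the shipped experiments

The corpus experiments in the test suite and in `scripts/acceptance.py` use
200 synthetic images (≈ 5–6 k candidates, ≈ 1 k spine rows), SCG capped at
400 iterations; a full run takes ~30 s on one CPU. Held-out test accuracy
on these corpora is 99–100 %, train/validation/test accuracies agree within
a few points, and the learned contrast matches the intended geometry: spiny
PD profiles rise and fall with ≈ 2 µm amplitude, non-spine PD stays flat
near the tube radius, non-spine PS is the steeper V, and spine backbones
are longer for true spines.

## Known limitations

* Single dendrite plane; no 3D, no time, no branching trees.
* Spines longer than the 2 µm minimum branch length merge into the backbone
  and are not detected (inherent to the minimum-branch-length rule).
* The synthetic accuracy figure is an analog of, not a substitute for,
  accuracy on real two-photon data.
* `smooth_surface` dilates objects by one pixel; masks are therefore
  slightly fatter than the binarization output, and measured spine-backbone
  lengths inherit ~1 px of that bias.
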