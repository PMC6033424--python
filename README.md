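# spinefind

Automatic identification of dendritic spines in 2D fluorescence microscopy
images.

Dendritic spines — micrometer-scale protrusions on neuronal dendrites — are
the postsynaptic sites whose structural changes underlie synaptic
plasticity. High-throughput live-imaging experiments (e.g. two-photon
imaging with glutamate uncaging) need spines found automatically, with no
per-image parameter tuning, in images whose brightness, background, and
spine morphology vary widely. `spinefind` addresses this for users of such
imaging rigs: the only required calibration is the pixel scale in px/µm.

## Method

The pipeline turns each grayscale image into a set of candidate spine
locations, describes each candidate by a 221-value shape/intensity vector,
and classifies the vectors with a small neural network:

1. **Binarization.** Intensities are min-max normalized to [0, 1] and
   median-filtered. Otsu's global threshold, reduced by 70% so no dim tissue
   is lost, marks certain background; the mean background level is
   subtracted. The mask is then formed by an adaptive local-mean threshold
   over a 10×10 µm neighborhood, and holes smaller than 0.5 µm² are filled.
2. **Backbone extraction.** The mask is thinned to a unit-width skeleton.
   Loop artifacts smaller than 0.5 µm² are filled and re-thinned; isolated
   segments with *p* < *M* pixels are deleted, where
   *M* = 2 µm × scale is the minimum branch length; remaining side branches
   shorter than *M* are removed by a recursive endpoint-peeling loop
   (endpoints near the border are protected), and kinks at former branch
   sites are straightened.
3. **Surface smoothing.** A majority filter (≥ 5 of the 3×3 neighborhood),
   morphological open–close–open, weak-pixel removal, diagonal fill, and a
   connection-preserving thickening make each component's perimeter a simple
   closed curve, so every perimeter pixel gets a unique travel position.
4. **Detached objects.** Components separated from the dendrite but within
   distance *M* of the backbone are triaged spine/non-spine by exact
   two-cluster k-means on their signal-to-noise ratios, then removed from
   all further processing.
5. **Features.** A geodesic distance transform of the mask seeded at the
   dendrite backbone assigns every tissue pixel its within-tissue distance
   from the centerline. Local maxima of this map along the perimeter are the
   candidates. Per candidate: **PD** — the geodesic values over a 5 µm
   perimeter window, resampled to 100 points and min-shifted to 0; **PS** —
   the same window against a transform seeded at the candidate's *spine
   backbone* (shortest within-tissue path from tip to dendrite backbone),
   100 points; **IS** — 20 image intensities interpolated along the spine
   backbone plus its length in µm. Together 100 + 100 + 20 + 1 = 221 values.
6. **Classification.** A feed-forward network (221 → 20 tanh → 2 softmax),
   inputs min-max normalized on the training split, weights initialized
   uniformly in [−1, 1], trained with Møller's scaled conjugate gradient on
   a 60/20/20 train/validation/test split with early stopping.

A synthetic image generator (curved tubular dendrite, stalk+head spines,
shallow non-spine bumps, PSF blur, signal-dependent noise, per-image ground
truth) makes every stage testable without microscope data.

## Worked example

```python
from spinefind import SynthSpec, generate, run_pipeline
from spinefind.workflow import corpus_experiment

img, gt, labels = generate(SynthSpec(seed=7))
print("ground-truth spine tips:", gt.spine_tips)
res = run_pipeline(img, rng_seed=0)
print("candidates:", len(res.features))
for f in res.features[:2]:
    print(f"  origin={f.origin}  dendrite_distance={f.dendrite_distance:.2f} um")

exp = corpus_experiment(40, seed=3, max_iter=300)
r = exp.reports["test"]
print(f"dataset: {len(exp.dataset)} candidates "
      f"({exp.dataset.n_spine} spine / {exp.dataset.n_non_spine} non-spine)")
print(f"test: accuracy {r.accuracy:.1f}%  TPR {r.tpr:.1f}%  "
      f"TNR {r.tnr:.1f}%  precision {r.precision:.1f}%")
```

prints

```
ground-truth spine tips: [(76, 81), (83, 49), (35, 44)]
candidates: 32
  origin=(65, 23)  dendrite_distance=0.62 um
  origin=(63, 26)  dendrite_distance=0.60 um
dataset: 1093 candidates (197 spine / 896 non-spine)
test: accuracy 100.0%  TPR 100.0%  TNR 100.0%  precision 100.0%
```

The 32 candidates are every local maximum of the dendrite-distance map along
the perimeter: the three true spine tips (distances ≳ 1 µm from the
centerline) plus tube-edge ripples and bumps near the 0.6 µm tube surface —
exactly the spine/non-spine contrast the classifier learns. On the 40-image
corpus the held-out test split is classified perfectly; larger corpora land
between 99% and 100%.

The same flow is available from a shell:

```
spinefind synth --n 200 --seed 42 --out corpus/
spinefind train --images corpus/ --labels corpus/labels.csv \
    --seed 7 --out model.json --report metrics.json
spinefind detect corpus/synth-00001234.tif --model model.json \
    --out points.csv --overlay overlay.png
```

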