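# Methods

## Problem setting and model

`patchseg` performs marker-controlled instance segmentation of tightly clumped
cells without manual annotation. The inputs are a multi-channel 2D field
(fluorescence `FL`, bright-field `BF`, optionally a nucleus stain `NUC`), one
marker per cell, and a field-wide binary cell-area mask `M`. The segmentation
network never sees a labeled cell; supervision is replaced by three structural
facts: cells tile the cell-covered area, two cells cannot own the same pixel,
and no cell extends outside `M`.

### Patch construction

Each marker is assigned a k×k window placed so the marker sits at index
(k/2, k/2) (0-based, row-major, half-open windows). Windows that would leave
the field are shifted minimally inward rather than padded, so no image content
is fabricated; the positional Gaussian-disk channel
`exp(−‖p − marker‖² / 2σ²)` (peak 1) is always drawn at the marker's true
in-window offset, which is what tells the network which cell to segment.
Defaults: k = 64, σ = 15 px; the desk-scale study uses k = 32, σ = 8 (all
patch-geometry quantities halved together).

### The objective

For patch predictions y¹…yⁿ, each treated as zero outside its window,

L = −Σ yⁱ − λ Σ_{i≠j} yⁱ log₁₀(1 − yʲ) + β Σ yⁱ (1 − M),

summed over field pixels (sums, not means — ADAM's per-parameter scaling makes
the distinction immaterial to the optimum, and sums keep the printed balanced
weight meaningful). The consistency term is a cross-entropy of each claim
against the *complement* of every overlapping partner's claim, counted over
ordered pairs; the pair summand vanishes identically outside window overlaps,
so the implementation iterates only over overlap rectangles, and a naive
zero-padded full-field evaluation is kept in the test suite as the oracle
(agreement to 1e−9).

Logs are base 10: with that convention the balanced weight — the λ at which
claiming a pixel whose partner claims 0.5 is exactly net-zero — is
1/(−log₁₀ 0.5) = 3.3219 ≈ 3.32, the package default. β defaults to 15, a
stiff penalty that keeps claims inside the mask without dominating early
training. Probabilities are clipped at eps = 1e−6 before any logarithm. In
the differentiable path the clip is applied only *inside* the log (standard
cross-entropy stabilization): clipping the linear area term as well would
gate its gradient and make the all-background state absorbing — a failure
mode we observed directly (see "Numerical choices").

### Network and training

The segmentation engine is a skip-connected encoder–decoder (UNet family):
`depth` stages of two 3×3 conv + batchnorm + relu blocks with 2×2 max-pooling,
a bottleneck, mirrored nearest-neighbor upsampling with skip concatenation,
and a 1×1 conv + logistic head. Output spatial size equals input size; the
single channel is a per-pixel cell probability. Filters double per stage from
`base_filters` (default 32; desk scale uses depth 2, base 8). He-normal
initialization from one seeded generator; batch statistics are always the
current batch (the models train and predict on full patch batches).

Training groups markers into square tiles (default 640 px); one tile = one
batch = one ADAM step (constant lr 0.005, β₁ = 0.9, β₂ = 0.999, decoupled
weight decay 1e−4). Per epoch every tile is visited in row-major order. Each
patch gets an independent dihedral augmentation (row flip, column flip,
transpose, each with probability 1/2); the exact inverse geometry is applied
to the network output before the loss, so the loss always acts in field
coordinates. Patch pairs in different tiles never interact within a batch —
a faithful, documented limitation of tile batching. Stopping: the run ends
when the relative decrease of the epoch-mean total loss stays below
`rel_tol` = 1e−3 for `patience` = 5 consecutive epochs, or at `max_epochs`
(a concrete stand-in for "train until the loss is stable").

### Mask generation

Fluorescence path: percentile normalization into (eps, 1−eps), then exact
graph-cut minimization of

E(y) = Σ S(yᵢ) + Σ_{(i,j)∈C} κ·[yᵢ ≠ yⱼ],  S = −log(α xᵢ) for foreground,
−log((1−α)(1−xᵢ)) for background,

on the 4-connected grid (8-connectivity available). The pairwise term is read
as a Potts cost — a signed difference is not a valid energy. α is the prior
foreground fraction, supplied as a coverage hint and clamped to [0.05, 0.95];
κ defaults to 1.0 and is an exposed knob. The unary model reads x as a
foreground likelihood, so the default *high* normalization percentile is tied
to the coverage prior (≈ the background fraction plus margin, clamped to
[50, 99]) rather than a fixed 99: with a fixed 99th percentile, genuinely dim
cells normalize mid-range and are cut out wholesale. The cut is solved with
`scipy.sparse.csgraph.maximum_flow` on capacities scaled by 2²⁰ to int64;
s-side of the residual graph = foreground. Exactness is asserted against
exhaustive enumeration on 3×4 instances.

Bright-field path: gray values carry no foreground contrast, so a two-class
random forest (50 trees, seeded) is trained on user scribbles with
Gaussian-smoothed intensity, local variance and Laplacian features at scales
(1, 2, 4, 8) px, and the graph cut runs on its calibrated foreground
probability.

### Markers

From a real nucleus stain: Otsu threshold → connected components → centroids
(one marker per component, duplicates after rounding nudged apart), or
difference-of-Gaussians blob detection: 6 geometrically spaced scales in
[2, 8] px, 3×3×3 local maxima above 0.04, maxima closer than a merge radius
(default: the smallest scale) merged keeping the strongest.

Without a nucleus channel: an encoder–decoder of the same family (depth 2,
base 8, single input channel) is trained to map the cell image to the
Otsu-binarized nucleus image with mean per-pixel natural-log cross-entropy,
ADAM lr 0.005, on random 32×32 crops (8 per batch, 4 steps per epoch),
stopping when the epoch-mean loss reaches 0.15 — the translation only needs
to place blobs, not render nuclei. Full-field inference tiles the image with
50%-overlapping windows and averages. Blob detection on these synthetic
nucleus images uses a higher threshold (0.08) and a 14 px merge radius:
predicted blobs are lumpy and otherwise yield duplicate maxima inside one
nucleus, which the pairing step would count as false positives; the merge
radius, safely below the minimum nucleus spacing, removes the duplicates.

Marker sets are scored by greedy nearest-first one-to-one pairing in physical
units with a 15 µm cutoff; FN = unmatched reference fraction, FP = unmatched
predicted fraction, each defined as 0 when its denominator is empty. Greedy
pairing (not optimal assignment) is deterministic and near-optimal at these
densities.

### Integration and evaluation

Each pixel goes to the marker with the highest covering-patch probability;
if every covering patch is below 0.5 the pixel is background; ties break to
the smallest marker id (deterministic, order-independent). For evaluation,
each reference cell is matched to the machine segment with maximal pixel
intersection (no exclusivity — one machine segment may match several
reference cells), per-cell IOU = |A∩B|/|A∪B|, and mIOU is the mean over
evaluated reference cells. Cells are classed as clump-edge vs interior by
whether more than 5% of their boundary touches background — used to verify
that removing the mask (β = 0) degrades edge cells more than interior ones.

## The synthetic-scene generator

Real data for this method are confluent monolayers; the generator emulates
exactly the structure the method relies on and nothing more:

- **Geometry.** Anchors rejection-sampled with a minimum spacing (default
  20 px); a foreground support region from a smoothed union of per-anchor
  radius fields, thresholded at the coverage quantile (default 50%, clipped
  to [0.5, 0.9]) so cells touch and real background exists; cell shapes by
  competitive priority-flood from the anchors with per-cell random speeds —
  regions are 4-connected and contain their anchor by construction.
- **Scale.** Default 48 cells on 256×256 at 50% coverage gives cell diameters
  ≈ 28 px, deliberately *smaller* than the 32 px desk-scale patch: the method
  assumes the patch exceeds a single cell, and its integration step can only
  label pixels some window covers. (At ~20 cells on the same field, cells
  would exceed the patch and perfect in-window predictions would cap mIOU at
  ≈ 0.65 — a geometric ceiling, not a model failure.)
- **Appearance.** `FL`: per-cell random base intensity (0.35–0.95) times
  smooth texture on a 0.05 background; `BF`: flat 0.55 gray with dark ridges
  along boundaries (drawn inside the cells, as the refractile cell rim is
  cell material) and weak interior texture, so thresholding cannot mask it;
  `NUC`: one elliptical Gaussian blob per anchor (radii 4–8 px). Both FL and
  BF carry a faint nucleus imprint — real cell images show their nuclei, and
  that visibility is precisely what makes image→nucleus translation
  learnable. Additive Gaussian noise (sd 0.03) clipped to [0, 1]; Poisson
  statistics, shading fields, debris and photobleaching are *not* modeled.
- **Units.** pixel_size defaults to 1 µm/px so µm-denominated thresholds
  (the 15 µm pairing cutoff) are directly exercised.

What passing tests therefore show: the objective, masking, marker and
integration machinery interact as designed on data with the assumed
structure. What they do not show: robustness to uneven illumination, imaging
noise statistics, cell-type morphology variation, or mis-set pixel sizes on
real microscopes.

## Numerical choices

- Probability clip eps = 1e−6; in the training loss the clip sits only inside
  the logarithms (see above). Near-saturated partners can still spike the
  consistency gradient to ~λ/eps; ADAM's second moment absorbs transients,
  and an optional elementwise gradient clip exists in the optimizer
  (off by default).
- Without normalization layers, the early training phase — where the
  consistency and mask terms jointly suppress all claims — can drive the
  logistic head into exact float64 saturation, where training is dead.
  Batchnorm in every conv block prevents the collapse and is the default;
  it can be disabled per config.
- Graph-cut capacities are rounded at scale 2²⁰; ties inside that quantum are
  broken by the solver deterministically. Degenerate inputs: a constant image
  normalizes to 0.5 everywhere; κ = 0 reduces to the per-pixel MAP rule;
  uniform labelings are returned as such.
- Even-k patch "center" is index (k/2, k/2); marker-at-border windows shift
  inward; integration ties break toward the smaller marker id.
- All randomness (scene synthesis, initialization, augmentation, crop
  sampling) flows from explicit integer seeds through `numpy` generators;
  identical seeds reproduce runs bit-for-bit except where floating-point
  non-associativity in BLAS reductions makes equality only approximate.

## Design choices made where the design was open

- No single layer stack is canonical for this task; a generic configurable
  encoder–decoder carrying the hard contracts (same-size output, probability
  head) is used, with depth and width as config knobs.
- The consistency term compares yⁱ against log(1 − yʲ): comparing against
  log yʲ would assign *zero* penalty to mutually claimed pixels and cannot
  enforce exclusivity. The mask term is a positive penalty; a negative sign
  would reward background claims. Base-10 logs are forced by the 3.32
  balanced-weight identity.
- "Stable minimum" stopping is concretized as patience-on-relative-improvement
  (rel_tol 1e−3, patience 5).
- One ADAM step per tile per epoch; epoch count, not step count, is the
  budget knob.
- DoG scale range, thresholds and merge radii were fixed on the synthetic
  fixtures (the generator defines nucleus sizes, so the choice is a
  consequence of the fixture design, and each is an exposed config knob).
- Marker extraction and scribble classification are native code
  (Otsu + connected components + centroids; a sklearn random forest) rather
  than calls into external GUI tools such as CellProfiler or Weka, keeping
  the pipeline scriptable and seedable.

## Known limitations

- Patch windows bound the segmentable area: a cell larger than k cannot be
  fully recovered, by construction (choose k above the largest cell).
- Tile batching severs consistency across tile boundaries.
- Batch-statistics batchnorm couples predictions within a batch; predictions
  are made in one full batch for order invariance, and a checkpoint reloaded
  elsewhere should be applied to comparable batch sizes.
- The translator is specific to the channel it was trained on; switching
  stains requires retraining.
- CPU-only: desk-scale runs (48 patches, depth 2, base 8, 200 epochs) take
  ~2 min; the implementation is not intended for full-resolution fields with
  thousands of markers.
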