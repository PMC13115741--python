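# Methods

`gliaquant` quantifies implantation-induced astrogliosis from 2D GFAP
immunofluorescence images. This note describes the models and procedures the
package implements, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices and known
limitations.

## Pixel classification

Segmentation follows the shallow-learning recipe popularized by
trainable-segmentation tools: each pixel is described by a feature vector of
filter responses, and a random forest is trained on the pixels covered by
sparse foreground/background scribbles.

**Feature stack.** The raw intensity (identity plane) plus, per scale
σ ∈ {1, 2, 4, 8} px: Gaussian smoothing, difference of Gaussians (σ vs 2σ),
Gaussian gradient magnitude, Laplacian, both Hessian eigenvalues, and local
min/max/mean over a (2σ+1)² window — 37 planes with all families enabled.
All filters use reflection padding, so features (and hence predictions) are
translation-equivariant away from borders. Second-derivative kernels are
sampled Gaussian derivatives shifted to exact zero sum, so derivative
features of a constant image are exactly zero (a truncated analytic kernel
leaves a ~exp(−8) residual). The largest scale must not exceed half the
smaller image dimension.

**Scribbles.** Polylines are rasterized with Bresenham line tracing (width 1
by default; larger widths dilate with a disk). Pixels claimed by both
classes are dropped from both and counted. Training requires at least 10
samples per class and a class imbalance no worse than 10⁴:1.

**Forest.** 100 trees, unlimited depth, √(n_features) candidate features per
split, seeded (default 0) and single-threaded, so that
(image, annotations, config, seed) fully determine the predicted mask. The
mask is foreground where the forest's foreground probability ≥ 0.5
(configurable). Models serialize to a single archive with a schema version,
the feature configuration, the seed/tree count and a SHA-1 fingerprint of
the training scribbles.

## Single-cell pipeline and morphometry

Per cell: a square ROI is cropped around a picked center (the square must
lie fully inside the image; no silent padding), segmented with a pre-trained
classifier, cleaned by removing 8-connected components below a size
threshold (default 30 px ≈ 2.7 µm² at 0.3 µm/px), composited with the raw
ROI by pixelwise minimum against the {0, max} mask image, and measured.
ROIs whose mask comes out empty are reported as failures, never silently
dropped.

Measurements (all surviving components contribute):

* **mean intensity** — over mask-true pixels of the raw ROI only, so the
  value does not depend on ROI size;
* **area** — true-pixel count × (pixel size)², in µm²;
* **perimeter** — Freeman chain-code boundary length traced through pixel
  centers (straight steps 1 px, diagonal steps √2 px), summed over all
  components and hole boundaries, in µm. This matches the particle-analysis
  convention of common interactive tools; a 10×10 px square measures
  36 px = 10.8 µm;
* **area-to-perimeter ratio** — exactly area/perimeter, in µm;
* **circularity** — isoperimetric quotient 4π·area/perimeter², 1 for a
  perfect disk. Because the chain code runs through pixel centers, values
  for objects much smaller than the default size filter can exceed 1 (a
  domino measures 6.3); a rasterized disk of radius 30 px measures ≈ 0.93.

The default pixel size is 0.3 µm (300 nm confocal sampling); it is carried
with every image and never parsed from TIFF tags.

## Process profiling

A process trace is an ordered polyline with its first vertex at the proximal
(soma-side) end. Traces are resampled at exact 1 px arc-length multiples
(count = ⌊L/spacing⌋ + 1; when the spacing exceeds the trace length, the two
endpoints are returned — the one place where the endpoint rule wins over the
count rule, since both cannot hold for lengths that are not multiples of
the spacing). Intensities are read by bilinear interpolation from the *raw*
image, not the mask composite, so compartment ratios are not censored where
segmentation misses thin distal stretches; a nearest-pixel sampler is
available for exactness checks.

Per process: mean intensity over all samples, over the proximal compartment
(first 10 samples = 3 µm at 0.3 µm/px) and the distal compartment (last 10
samples), the distal-to-proximal ratio, and length (n−1)·spacing·pixel size.
Traces shorter than 20 samples are flagged: the whole-process mean is still
computed, compartments are null, and they are excluded from ratio summaries
while still counting toward the per-cell process count. A zero proximal mean
flags the ratio as undefined rather than returning infinity.

**Mask coverage** of the process tree is the pooled fraction of resampled
trace points whose nearest pixel is mask-true — a length-weighted estimate
of how much of the traced arbor the segmentation captures.

## Agreement metrics and estimation statistics

Dice = 2|A∩B|/(|A|+|B|) and IoU = |A∩B|/|A∪B| from exact pixel-set counts;
two empty masks raise instead of silently scoring 0. Strategy validation
averages Dice/IoU per (strategy, animal) and then per strategy group.

Inference treats the animal as the unit: cell-level values are averaged per
(animal, condition) — groups under 10 cells are flagged — and the paired
per-animal differences (scar − non_scar) are summarized by their mean, a
seeded percentile-bootstrap 95% CI (default 10,000 resamples over animals,
never over cells), and Cohen's dz = mean(d)/SD(d) with sample SD. Benchmark
labels follow the conventional boundaries by |dz|: < 0.5 small, 0.5–0.8
medium, 0.8–2.0 large, ≥ 2.0 very large. Zero-variance differences flag dz
as undefined rather than reporting ±∞.

The percentile bootstrap was chosen over BCa for transparency at N = 4. Its
known cost is under-coverage at such small N: for normal differences the
nominal 95% interval covers at ≈ 79%. Relatedly, dz at N = 4 is pivotal
under a continuous null — dz ~ t(3)/2, so |dz| < 0.5 only ≈ 61% of the time
even for a perfect null generator; small-sample dz estimates are noisy and
their magnitudes should be read with that in mind.

## Synthetic data generator

No imaging data ships with the package, so all validation runs on generated
scenes emulating GFAP-stained astrocytes:

* **Cell model** — a soma disk (radius 6 px, intensity I₀ = 120 AU) with
  n = 5 correlated-random-walk processes of width 2.5 px and mean length
  32 px, rooted just inside the soma boundary. Intensity along a process is
  I₀·exp(−s/λ) with λ = 25 px, and a proximal-enrichment factor ρ ≥ 1
  multiplies the proximal third — the simplest intensity family that can
  raise both compartments while lowering the distal-to-proximal ratio.
  Branching is available (`branch_prob`) but off by default so that every
  emitted trace starts inside its soma. A walk that would leave the canvas
  is regenerated with bounded retries (after a few, with a free heading, so
  cells near the canvas edge remain renderable).
* **Optics and noise** — a faint halo (blurred copy of the cell, amplitude
  0.2, σ = 10 px) emulates out-of-focus light, making near-cell background
  brighter than far background (this is what gives the background-placement
  annotation rule its bite); scenes add a background level of 10 AU and
  Gaussian noise (SD 5 AU), clipped at zero. Ground-truth masks are the
  noiseless, halo-free render > 0.
* **Cohort design** — 4 animals × 2 conditions × 13 cells (~104 cells,
  the scale of the study design targeted) on 128 px canvases with 112 px
  ROIs. Scar cells are drawn with k_intensity = 1.3, k_area = 1.5 (on soma
  area), k_length = 1.5, two extra processes, ρ = 1.5 vs 1.0, and three
  distractor cells crowding the ROI margins (giving the size filter
  realistic work). Per-animal multiplicative log-normal jitter (σ = 0.08,
  shared between conditions) plus per-cell jitter (σ = 0.10) produce
  realistic paired variance at N = 4. Everything is deterministic under the
  master seed. The null configuration sets all multipliers to 1 and equal
  distractor counts, making conditions exchangeable by construction.
* **Scribble strategies** — `rule_compliant` follows the four annotation
  rules of thumb (non-scar cell; through the cell body and the longest
  process; bright and dim pixels; background alongside at a small gap,
  placed on the side clearest of other processes). Each rule-violating
  strategy breaks exactly one rule: `rv_core_only` (foreground restricted
  to a cross inside the bright soma core), `rv_far_background` (background
  hugging the farthest image corner), `rv_scar_trained` (compliant geometry
  on a crowded scar cell).

**What the generator does not emulate:** point-spread-function optics,
depth/3D structure, intensity saturation, spatially structured background
(vasculature, neighboring arbors outside distractors), inter-animal
staining batch effects beyond a scalar factor, and annotator variability in
manual traces. Passing tests therefore demonstrate that the pipeline
recovers known contrasts under this idealized forward model, not
performance on real tissue.

## Scripted experiments and problem sizes

`gliaquant.experiments` packages the analyses end to end: the
annotation-strategy validation (6 classifiers, a 25-cell test set — 17
scar, 8 non-scar — across 4 pseudo-animals), the whole-cell scar-contrast
pipeline (~100-cell cohort, one rule-compliant classifier trained on a
held-out cell), the process-level contrasts (ground-truth traces on raw
images), and repeated null cohorts (20 seeds, 10 cells per condition,
measured on ground-truth masks to isolate generator-plus-statistics
behavior from segmentation noise). These sizes are the package's desk-scale
defaults; all are configurable.

## Known limitations

* The chain-code perimeter (and hence circularity) is biased for objects a
  few pixels across; measurements are intended for cells well above the
  size-filter threshold.
* Percentile bootstrap CIs under-cover at N = 4 (≈ 79% for a nominal 95%),
  and dz point estimates at N = 4 are heavy-tailed (t(3)/2 under the null);
  see above.
* The classifier offers no probability calibration; the 0.5 threshold is a
  convention, not an optimum.
* Scribble strategies are deterministic geometric constructions; the `seed`
  argument is reserved for randomized variants.
* Intensity units are arbitrary; nothing assumes a specific bit depth
  beyond non-negativity.
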