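# Methods

## The synthetic skin model

Every validation in this package runs against generated H&E-like skin
rasters with exact ground truth. A sample is a three-layer stack: stratum
corneum (rows above `corneum_thickness`), the epidermis band, and dermis.
Before any rotation the epidermis–corneum boundary (ES) is the flat line
`row = corneum_thickness` and the epidermis–dermis boundary (EB) is the
sinusoid

    row = corneum_thickness + epidermis_thickness
          + ridge_amplitude * sin(2*pi*col / ridge_wavelength),

so `ridge_amplitude` is half the peak-to-trough excursion of the rete
ridges and the mask is exactly the set of pixel rows between the two curves.
Nuclei are dark-purple ellipses (semi-axes 2–4 px, i.e. 4–8 px full axes),
placed by rejection sampling (≤ 100 attempts each) so they do not overlap,
clipped to the band, at `nucleus_density` nuclei per 10⁴ epidermis pixels.
The default density is 60 — with ~28 px² ellipses that covers roughly a
sixth of the band, enough texture for co-occurrence statistics while keeping
rejection sampling cheap. Additive Gaussian noise (default sd 4) is clipped
to [0, 255]. Orientation is applied last: the image is rotated with
reflective padding, the mask with nearest-neighbour interpolation, and the
polylines analytically, so ground truth stays exact. Identical parameters
and seed give bit-identical output.

Cohorts jitter `epidermis_thickness` and `ridge_amplitude` per sample by a
10% relative Gaussian sd around the group means, with per-sample seeds
derived from the cohort seed. The default young/aged conditions encode the
three aging effects the morphometric and radiomic analyses target: aged
epidermis is thinner (20 vs 40 px), flatter (amplitude 3 vs 10 px) and less
cellular (30 vs 70 nuclei per 10⁴ px).

What the generator does **not** emulate: real chromatin texture, collagen
fibre structure, adnexal structures (a plain dark-blob distractor option
stands in for follicles/glands), scanner optics, or stain variability beyond
a global palette. Tests passing on this model therefore demonstrate
algorithmic correctness and internal consistency — not clinical performance
on real slides.

## Stain normalization

Optical density is `-log10((I+1)/256)`; the +1 avoids log(0) and puts pure
white at OD 0 exactly. Pixels with any channel below the transparency
threshold β = 0.15 OD are excluded from estimation, and pixels with *all*
channels below β are treated as background and pass through normalization
unchanged (white regions must not acquire a stain tint). The two stain
vectors are the extreme-angle directions (1st/99th percentile, α = 1) of
the OD cloud projected onto its two largest-variance directions; columns are
clipped to the non-negative orthant, unit-normalized, and ordered
hematoxylin-first by the larger blue-channel component. A rank-1 OD cloud
(single stain; second eigenvalue < 10⁻³ of the first) and near-blank images
raise a degenerate-input error. Concentrations are solved by least squares
clipped at zero (an exact per-pixel NNLS switch exists for verification);
normalization rescales them by the ratio of reference to source
99th-percentile maxima.

Accuracy caveat, quantified during development: the extreme-angle estimator
is only as good as the purest pixels present. When tissue contains near-pure
hematoxylin and eosin pixels, vectors are recovered to well under 1° and
self-normalization is identity up to ±2 intensity units; channel saturation
(OD beyond the 8-bit range) and the β-filter discarding light eosin-only
pixels are the error sources otherwise. Forward-model validation fixtures
therefore use β = 0.05 so that physically meaningful pure-eosin pixels
participate.

## Epidermis segmentation

The segmenter needs no annotation. Felzenszwalb superpixels (scale 100,
σ 0.8, min size 50) group visually coherent pixels; a small conv net
(default three 3×3 conv/ReLU/batch-norm blocks at 100 channels, then 1×1
conv + softmax) labels every pixel; each iteration the argmax labels are
replaced by the majority label within each superpixel and the cross-entropy
against those refined labels is backpropagated (SGD, lr 0.1). Iteration
stops when the refined labeling has at most `min_clusters` distinct labels
(default 3 — the least that can separate corneum/epidermis/dermis) or at the
iteration cap; the returned raster is the final superpixel-refined argmax
(raw per-pixel argmax leaves salt-and-pepper singletons that carry no
information the refinement step hasn't already resolved).

The epidermis cluster is chosen by the package's own heuristic — the source
procedure for this step is not public — maximizing (mean hematoxylin OD) ×
(elongation of the largest connected component), restricted to clusters
whose largest component reaches the refinement area floor; scattered
nucleus-pixel clusters otherwise win on stain density alone. An explicit
`cluster_id` override bypasses the heuristic. Cleanup is morphological
opening (disk radius 3) plus removal of components below 256 px (200 px at
the 128-px benchmark scale).

Level-1 extraction: if the mask's principal axis deviates more than 20° from
a raster diagonal the image and mask are rotated to align it, then the mask
is accepted iff (a) one connected component of its tight bounding-box crop
reaches both corner regions (squares of side 0.15·min(H, W)) of either
diagonal and (b) the mask fills at most 60% of that box. The fill criterion
is needed because any box-filling compact blob trivially "spans" its own
box; diagonal bands fill little of theirs. Rotation must precede the test:
a horizontal band can never touch diagonal corners.

Benchmark scale: 128×128 rasters, 16 channels, 2 conv blocks, ≤ 60
iterations — about one second per sample on one CPU, mean IoU ≈ 0.94
against ground truth over seeded samples.

## Patch sampling

The sampling path is the longest path through the mask skeleton
(double-BFS diameter approximation, deterministic lexicographic
orientation). Level-2 centers sit every `stride2` arc-length steps along
that path (stride defaults to the patch size — non-overlapping — since no
canonical overlap exists); a center whose crop would cross the raster border
shifts *along the path* to the nearest fitting path point (ties toward the
raster center), which keeps every center on the mask; duplicates after
shifting are dropped; a path shorter than one stride yields a single
midpoint patch. Crops are half-open `[r, r+s) × [c, c+s)` in 0-based
(row, col) coordinates.

The BMZ inclusion filter accepts a level-2 patch iff its mask fraction lies
in [0.1, 0.9] (both epidermis and non-epidermis present) and the mask's
principal axis is within 25° of a patch diagonal. Level-3 patches repeat the
center-along-path procedure inside the level-2 crop along the EB-side
boundary — the side of the mask adjacent to the dermis, where the BMZ lies —
falling back to the skeleton midline when the crop's boundary cannot be
split into two sides.

## Morphometrics

Boundary extraction projects every boundary-contour point onto its nearest
skeleton-path point; contour points projecting into the first or last
`half-width + 2` path indices belong to the band's end caps and are
discarded; the two longest remaining circular runs are the band's sides.
Masks whose boundary does not produce two long sides (disks, blobs) raise a
topology error. Role assignment: with pixel data, the side whose 10-px outer
band carries more hematoxylin OD is EB (dermis stains darker than corneum);
without pixels, the more undulating side (arc length per unit chord) is EB.
Both rules agree on the synthetic model.

Both boundaries are resampled at 1-px arc steps (the index sets are
otherwise arbitrary); distances are exact point-to-segment minima
(cross-checked against an independent geometric library in the tests);
thickness is the mean of ES→EB distances and the rete ridge score the
population variance (divisor *n*; at n ≈ 10³ the sample/population
difference is negligible) of EB→ES distances. The definition is asymmetric
on purpose and the implementation does not symmetrize it. A numerical note:
arc-length resampling weights the steep flanks of the ridges more than
uniform-in-x sampling would, so for a sinusoid of amplitude A the score sits
a few percent below the uniform-in-x limit A²/2; the tests compare against a
dense numeric oracle computed under the same convention.

## Radiomics

Patches are converted to luminance grayscale (0.299 R + 0.587 G + 0.114 B)
and discretized at a fixed bin width of 25 intensity units from the region
minimum. The schema is pinned at exactly 106 named features: 13 numeric
diagnostics, 18 first-order statistics (Entropy and Uniformity on the
discretized histogram, the rest on raw gray values), 24 co-occurrence (GLCM)
features from the average of the four symmetric distance-1 angle matrices,
16 run-length (GLRLM) features from the direction-summed run matrix, 16
size-zone (GLSZM) features with 8-connected zones, 5 neighbouring gray-tone
difference (NGTDM) features, and 14 gray-level dependence (GLDM) features
with dependence size = (count of neighbours within α = 0 levels) + 1.
Non-finite values (e.g. skewness of a constant patch) become 0 and are
flagged, keeping vectors rectangular. Features default to the full patch;
a mask-restricted mode exists. Extraction of a 512×512 patch takes ~2 s on
one CPU and is bit-deterministic.

The random-forest explorer (500 trees by default; smaller forests in
fixtures) ranks features by impurity importance normalized to sum 1 and
reports the top 5. All cross-validation is grouped by slide id so patches
from one slide never straddle a split.

## Classification

Slides are the unit of data splitting: `make_folds` stratifies slide ids by
label into k = 5 folds (80/20), and `evaluate` re-asserts on every fold that
no test slide appeared in training. Training is plain SGD at learning rate
0.01 with mini-batch size 1 and cross-entropy loss on per-channel-normalized
input ((x/255 − 0.5)/0.25); epochs default to 10 (12 in the aging study —
the point where the fixture-scale nets plateau).

Backbones: `small_cnn` (three conv stages with batch norm, GAP, linear
head), `plain_cnn` (the same without normalization) and `resnet_small`
(residual variant, exercised by a smoke test). All run on the package's
numpy engine, whose analytic gradients are verified against finite
differences in the test suite. Pretrained weights are not bundled;
requesting them raises. One engine detail matters scientifically: at
mini-batch 1, batch normalization *is* instance normalization, and
inference must normalize with the same per-sample statistics it trained
with — using running averages instead was observed to invert learned
features on held-out data (fold AUC 0.11 on a problem the model had
actually solved). `use_batch_stats_at_eval` is therefore enabled whenever
`batch_size == 1`.

Metrics: accuracy, trapezoidal ROC-AUC, PR-AUC by the step-wise precision
envelope (each recall level gets the best precision achievable at or above
it — this dominates raw step integration), macro-F1; multi-class AUCs are
macro-averaged one-vs-rest; a single-class test fold reports its AUC as
absent without affecting pooled metrics.

### Study designs and the chance control

The **aging study** (10 + 10 slides, 192×192 px, 64-px patches at stride 24,
~150 patches) reaches pooled out-of-fold accuracy ≥ 0.95 across seeds. The
**chance study** re-runs the pipeline with *identical* generative conditions
in both groups. A subtlety: with few slides, out-of-fold AUC under slide
grouping has a Mann-Whitney sampling sd of ~0.13 at 10+10 slides, so a
single run cannot meaningfully certify "chance level". The chance study
therefore uses 100 + 100 small slides with one patch each (making patch
scores effectively independent) and is averaged over three seeded
repetitions; the resulting mean AUC has sd ≈ 0.02.

## Hotspot tracing

`gradcam` is standard: channel weights are the spatial mean of the gradient
of the target-class logit (a loss-gradient mode exists) at the last spatial
layer (a first-conv tap is available as an option — useful when the
discriminative texture is fine-grained — though the last-layer map remains
the default, as the deeper features are the ones the classifier actually
pools); the map is the ReLU of the weighted activation sum, min-max
normalized with an all-zero guard, bilinearly upsampled.

For *localization analysis* on binary models the package provides the
class-contrast map `|Σ_c (w_c^A − w_c^B) A_c|` (no ReLU). The sign of the
discriminative projection is an arbitrary outcome of training — evidence
"for young" and "against aged" are the same evidence — so single-class maps
localize on one side or the other unpredictably, while the contrast map is
polarity-invariant.

The **localization study** uses a matched-geometry cohort: both groups share
thickness (24 px) and amplitude (6 px) distributions and differ only in
cellularity (70 vs 25 nuclei per 10⁴ px). This is deliberate: when groups
differ in band geometry, the class evidence necessarily straddles the
junction (a thin band is evidenced by dermis where the band is absent), and
"heat inside the mask" is not a well-posed expectation. With all class
signal strictly intra-epidermal and the normalization-free backbone (batch
norm injects global image statistics into every spatial position, smearing
the map), the inside-vs-outside test is meaningful: the contrast map puts
more heat inside the epidermis mask than outside in ≥ 95% of held-out
patches across seeds.

## Problem sizes

All study scales (128-px segmentation rasters, 192-px cohort slides, 64-px
patches, 10 + 10 slides, ≤ 12 epochs) are the package's chosen benchmark
conditions: large enough that each property is measured with useful
precision, small enough that the entire validation suite runs on one CPU in
minutes. The same code paths accept full-resolution inputs; the tile-level
interface (arrays in, arrays out) is the integration point for pyramidal
WSI readers, which are out of scope here.
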