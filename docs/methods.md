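# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the known limitations of the estimators.

## Coordinate and unit conventions

All geometry lives in the image frame: coordinates in micrometres, y
increasing downward, cortical depth measured from the pia ("Outside
Pia") contour. Densities are cells/mm³, computed from areas in µm² and
the slice thickness T (default 50 µm) as count / (area × T × 1e-9).
Tables are tab-separated in the QuPath detection-export dialect; header
matching is case-insensitive and tolerant of µ/μ/u spellings because
real exports vary. Region annotations are GeoJSON FeatureCollections
with the classification name in `properties.classification.name` or
`properties.name`; polygon exteriors are normalized counter-clockwise on
read, which makes region area orientation-invariant. A missing soma
area is back-filled as π·((d_max+d_min)/4)² and flagged.

## Stereological exclusion

The model assumes cells are spheres of unknown depth inside the slice.
Each cell receives an independent virtual z ~ U(0, T); its diameter is
estimated as the unweighted mean representative diameter
((d_max+d_min)/2) of its six nearest in-plane neighbors, excluding the
cell itself — the neighborhood estimate is deliberately independent of
the cell's own segmentation. A cell is excluded when z + d/2 exceeds T
*strictly*: a cell exactly tangent to the surface counts as inside (the
conservative reading of the rule; the boundary event has probability
zero under continuous z anyway). For any diameter distribution with
d ≤ 2T the excluded fraction has expectation E[d]/(2T), which the test
suite verifies by Monte Carlo.

The z assignment is bootstrapped (default 100 iterations; the neighbor
diameters are computed once since the in-plane geometry never changes).
Downstream stages consume the per-cell exclusion probability as an
effective inclusion weight 1 − P(excluded) rather than one exclusion
realization: this equals the bootstrap mean over iterations in
expectation and removes one source of Monte-Carlo noise.

## Nonlinear depth grid

The S1HL boundary is split at the four corner reference points into a
pia-side and a white-matter-side polyline. Both are resampled to 200
arc-length-uniform segments; the row at depth fraction t is the linear
blend (1−t)·top + t·bottom of corresponding points, and columns are the
straight segments joining top and bottom points at equal arc-length
fractions (the blend of two matched points traces exactly that
segment). Bins are the cells of this 10 × 20 curvilinear lattice clipped
to the polygon. Linear blending is the simplest construction that
follows both boundary shapes and reduces to uniform rectangular binning
for a rectangle, which the tests assert exactly. The construction is
well defined only for convex corner quadrilaterals; concave regions are
refused with an explicit error, mirroring their exclusion from the
analysis. Bin areas must tile the polygon within 0.5 % — clipping
slivers are the only loss — and every in-polygon cell is assigned to
exactly one bin (ties on shared edges go to the first covering bin;
cells in clipping slivers snap to the nearest bin). Row statistics
average the 10 columns within an image before any across-image mean/sd,
so each image contributes one curve regardless of its cell count; row
positions are reported at bin centers (2.5 %, …, 97.5 %).

## Layer classification

Features per cell: x, y, distance to pia, area, max/min diameter,
aspect ratio, circular-equivalent diameter, and each feature's
"smoothed 50 µm" counterpart — the unweighted mean over all cells of the
same image within 50 µm (self included, so a spatially constant feature
is a fixed point of smoothing and an isolated cell keeps its own
value). Feature selection uses permutation importance on a held-out
split (mean accuracy drop over repeated column permutations); only
features with positive mean importance are kept. On synthetic columns
the distance-to-pia features dominate, as expected for a laminar
classification problem.

Models are a KNN (k = 15, distance-weighted, standardized features) and
a random forest (500 trees, unlimited depth); these hyperparameters are
package defaults, overridable per call and echoed into reports.
Cross-validation folds are grouped by image — cells within an image are
strongly spatially dependent, and per-image splitting is what the
train/test protocol of the underlying study implies. Metrics come from
the fold-pooled confusion matrix; per-class accuracy is defined as the
fraction of the class's cells classified correctly, so the macro
accuracy is the balanced accuracy: chance level is 1/K under label
shuffling and every class weighs equally regardless of support (the
tests assert both, plus exact support-invariance of the macro metrics).
Both labeling paradigms are supported: LII and LIII separated, or
merged into LII/III.

## Alpha-concave layer hulls

The alpha shape of a layer's cells is the union of Delaunay triangles
with circumradius < 1/α; α = 0 keeps all triangles (convex hull) and
increasing α tightens the outline. This is the characteristic-scale
convention of the common alpha-shape toolbox; the defaults α = 0.05
(all layers) and α = 0.005 (Layer I, one tenth, reflecting its much
lower density) are exposed in configuration because conventions differ
between implementations. The largest connected component is returned
with interior holes filled, and cells on the hull boundary count as
inside. `select_alpha` returns the candidate giving minimal hull area
subject to rejecting no cell, falling back to the convex hull with a
warning when no candidate qualifies. Hull area is non-increasing in α
until cells start being rejected.

**Known bias.** The hull shrinks to the data, losing a boundary margin
of roughly one inter-cell spacing (~0.7/√λ_areal) along each edge, so
the density n/(hull area × T) is biased upward by approximately
perimeter × margin / area. For square-ish slabs with thousands of cells
this is 2–3 %; for thin cortical bands (LI, LII, LVIb at ~130–165 µm
height) the two long edges dominate and the inflation reaches 15–25 %
regardless of how wide the band is. This is a property of the
estimation method itself, not of the implementation; the end-to-end
tests encode this method-aware expectation rather than an unconditional
recovery bound.

Layer heights: along each grid column, the boundary between adjacent
layers is the depth split minimizing misplaced labels (equivalently the
majority-switch point; in the noise-free limit, the midpoint between
the last cell of the upper layer and the first of the lower). The top
of Layer I is the pia (depth 0) and the bottom of the last layer its
deepest cell. This rule is deterministic, testable, and exact for
noise-free labels; heights aggregate as mean ± sd over columns and
images, and the per-layer means add up to the total column height.

## Morphometry and statistics

Diameters assume circular somata, d = 2√(A/π). The 2-component
Gaussian mixture is fitted by EM with full per-component variances,
initialized by a below/above-median quantile split plus 5 random
restarts (best log-likelihood kept, components sorted by mean; the
fit is deterministic given the seed). With heavily overlapping
populations the wide component's mean is estimated with noticeable
upward bias at n = 5,000 — the narrow small-cell component absorbs part
of its left flank — while the small-cell mean is recovered to a few
hundredths of a micrometre; an overlap flag marks fits whose component
separation is below the larger sd. Across-image aggregation averages
the per-image population means unweighted and compares the two
populations with a two-sample t-test in the Welch (unequal-variance)
flavor for consistency with the rest of the battery; a pooled-variance
option exists. Degenerate inputs follow explicit conventions instead of
erroring: identical samples give t = 0, p = 1; an all-ties
Kruskal–Wallis gives H = 0, p = 1, flagged. Adjacent-layer density
comparisons run the six ordered pairs at α = 0.05/6.

## Segmentation metrics

Matching is greedy on descending pairwise IoU above a 0.5 threshold
(configurable), with deterministic tie-breaking; unmatched predictions
are FP, unmatched references FN. The greedy rule is the common
convention where the exact matching protocol is not prescribed; on
jittered-square benchmarks it agrees with the optimal-assignment oracle
whenever IoU ties are absent. Scores are computed on polygon areas in
the vector domain; an optional rasterization mode at a stated pixel
size (default 0.346 µm) supports bit-comparable pixel-counting studies.

## Synthetic columns

The generator emulates: a curved cortical band (pia as a circular arc
of adjustable sagitta; layers as constant-normal-distance offset bands,
so depth equals distance-to-pia), per-layer homogeneous Poisson cell
counts with intensity × band area × T expectation, per-layer
2-component Gaussian diameter mixtures truncated at 0.39 µm, and the
exported table/GeoJSON formats. The packaged defaults are the reference
per-layer heights, densities and mixture parameters for the juvenile
rat S1HL; the mixture weights are not part of that reference set and
default to 0.5. Randomness is driven by one global seed with a named
sub-stream per layer (stable under edits to the layer list).

It does **not** emulate: pixel data or staining intensity, segmentation
errors or split/merged cells, within-layer density gradients, cell
aggregates near the pia, anisotropic or clustered point patterns, or
non-circular somata beyond a symmetric max/min diameter eccentricity.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to segmentation artifacts in real
images.

## Problem sizes

The test suite uses reduced columns (250–2,000 µm wide, 2–20 k cells)
chosen so that per-layer point counts are large enough for stable hulls
while the whole suite runs in well under a minute per module; the
acceptance script averages 20 independent 1,000 × 500 µm slabs per
density target and one n = 5,000 diameter sample for the mixture
target.

## Known limitations

* The alpha-hull density estimator's thin-band inflation (above) means
  per-layer densities of LI/LII/LVIb are systematically high relative
  to the generating intensity under the default α values.
* Layer-height estimation assumes labels that are majority-correct per
  column; heavily shuffled labels produce large column-to-column sd (a
  sanity alarm asserted in tests) rather than a failure.
* The exclusion model treats cells as spheres with the neighborhood
  diameter; elongated somata near the surface are only approximately
  handled.
* Concave S1HL regions are refused, not re-parameterized.
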