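# Methods

This note documents the models, parameters and numerical choices behind
`pdl1score`, in the spirit of a methods supplement: enough detail to
re-derive every default and to know what the synthetic validation does and
does not demonstrate.

## Stain model

Brightfield chromogens are absorptive, so per-channel optical density
`OD_c = log10(background_c / max(I_c, 1))` (clipped at 0) is linear in stain
amount. log10 is used so DAB thresholds sit on the scale common in the IHC
quantification literature; intensity 0 is treated as 1 to avoid infinities,
and OD is clipped below at 0 (a pixel brighter than the white point carries
no stain). Stain separation is a per-pixel least-squares projection of the
OD 3-vector onto unit stain vectors with negative loadings clipped to zero.
The default basis is the Ruifrok–Johnston H-DAB basis (hematoxylin
[0.650, 0.704, 0.286], DAB [0.269, 0.568, 0.778], residual = normalized
cross product); it is configurable, and no attempt is made to estimate
vectors from the image (Macenko-style estimation and cross-scanner color
normalization are out of scope). The white point is estimated as the modal
intensity per channel among pixels whose luminance lies in the top decile —
the glass region — and an image with no pixel above luminance 100 is
rejected so the caller can supply an explicit white point.

Round-trip guarantees: OD → RGB → OD is exact up to 8-bit quantization
(≤ 1 intensity level on re-rendering); adding the deconvolution step keeps
every pixel within 2 levels, because quantization noise is amplified by the
inverse stain matrix at dark pixels.

## Tumor-region detection

The hematoxylin channel is tiled at a physical edge of 256 µm. The default
stride equals the tile size (non-overlapping); with an overlapping stride,
labelmap cells live at stride resolution and each window casts a
maximum-probability vote on every cell it covers — deterministic and
order-independent. Partial edge tiles are dropped.

The tile classifier is an interface: anything with `predict_proba` over the
eight tissue classes can be plugged in. The default implementation computes
21 scale-aware texture statistics per tile (OD quantiles and exceedance
fractions, blob density/size/eccentricity/solidity, blob circularity and
Euler number per blob, nearest-neighbor distance statistics of blob
centroids, gradient magnitude and structure-tensor orientation coherence)
and feeds a one-hidden-layer MLP (48 logistic units, L2 1e-4). Statistics
are computed in µm, so a model transfers across pixel calibrations. A
convolutional architecture would be a drop-in replacement behind the same
interface; the feature-based default keeps the package dependency-light and
fully deterministic per seed.

Labelmap cleanup removes 8-connected components smaller than 4 tiles and
fills interior holes of up to 4 tiles. Hole filling is implemented directly
(label the background 4-connected, fill small components that do not touch
the map border): off-the-shelf "small hole" removal also fills
border-touching bays, which are not interior gaps and must survive. The
cleaned labelmap is polygonized as the union of tile boxes in µm
coordinates (origin top-left, x rightward, y downward), so the polygon area
equals positive-tile-count × tile-area exactly; the annotation exports as a
GeoJSON FeatureCollection with `{"classification": "Tumor"}`, importable
into QuPath. Artifact exclusion (folds, pen marks, carbon) is explicitly
not attempted.

## Nucleus detection and cell geometry

Detection uses the hematoxylin channel only — adding DAB signal never
changes it. The default detector: Gaussian smoothing (σ = 1 µm), a triangle
threshold over in-region intensities floored at OD 0.15, hole filling, then
a distance-transform watershed whose markers are EDT maxima at least 3 µm
apart and at least 2 px from the boundary. The triangle threshold replaces
the more common Otsu choice deliberately: with mixed-intensity nuclei
(pale elongated stromal vs dark immune) and a small foreground fraction,
Otsu settles between the nuclear classes and drops the pale ones, while the
triangle rule tracks the background shoulder. Each watershed object is then
refined to its half-max boundary on the *unsmoothed* channel (the smoothed
mask overshoots the true edge by roughly the smoothing radius, which would
bias nucleus areas upward by ~30% and misplace the membrane band), and
objects outside [8, 400] µm² are discarded. Objects become 32-ray
star-convex polygons around their centroid (radius per angular bin = max
pixel distance + half a pixel; empty bins inherit the nearest non-empty
ray). Detections are sorted by (y, x) and the whole stage is deterministic.
A pre-trained star-convex deep detector can be substituted by producing the
same `NucleusShape` list.

Cells are nucleus polygons expanded by 5 µm, with every pixel assigned to
its *nearest nucleus* (Euclidean distance transform with index return) and
clipped to the tumor region — influence zones of the nucleus boundary
rather than a Voronoi diagram of centroids. This matches the convention of
brightfield cell-expansion tooling, guarantees exactly zero overlap between
cells even for elongated nuclei, and runs in raster space in O(pixels). A
half-pixel margin is added to the expansion radius because the EDT measures
center-to-center while the expansion is meant to the pixel footprint. The
membrane is the inward band of 1 µm at the cell boundary (excluding nucleus
pixels); the cytoplasm is the remainder, so the three compartments
partition the cell exactly. With zero expansion the cell equals the nucleus
and the membrane falls back to the nucleus-boundary band, flagged per cell
and surfaced in the report. Neither the 5 µm expansion nor the 1 µm
membrane thickness has a canonical published value; both follow common
brightfield practice and are exposed in the configuration.

## Features and cell typing

Per cell: areas (cell, nucleus, µm²), circularity 4πA/P² (crofton
perimeter, clipped to 1.05 for rasterization), nucleus solidity, min/max
diameters (ellipse-fit minor axis and max Feret, µm), nucleus/cell area
ratio, and per compartment (nucleus, cytoplasm, membrane, cell) × stain
(hematoxylin, DAB) the mean, median, min, max and standard deviation of OD
("dispersion" is interpreted as standard deviation). Compartments smaller
than 4 px inherit the cell-level statistics. Neighbor smoothing appends,
for every raw feature, the Gaussian-weighted mean over cells within 25 µm
(w = exp(−d²/2σ²), σ = radius/2, self included — a config flag excludes
self) plus the count of other cells in the radius; smoothing is a convex
combination and uses a KD-tree. Column names are canonical and stable so
model weights and importance tables stay aligned.

The cell-type MLP (32 logistic hidden units, L2 1e-4, ≤ 500 iterations,
standardization inside the model with zero-variance guards) classifies
cells as tumor / immune / stromal; training reports a stratified held-out
accuracy and 3×3 confusion matrix, and optional per-class resampling
equalizes class counts. By default DAB-derived features are excluded from
typing (flag to include): cell identity should rest on morphology and
hematoxylin staining, not on PD-L1 expression, or the model would fail to
transfer between high- and low-expressing slides. Inference is an explicit
forward pass over the stored weight matrices, so the JSON serialization
(versioned header + arrays) reproduces probabilities bit-exactly, and Olden
variable importance — importance(i, c) = Σ_h w_ih·w_hc on the
standardized-scale weights — reads the same arrays. Importance is defined
only for a single hidden layer; standardization makes values comparable
across features measured in µm, µm² and OD.

## Scoring

Tumor cells are judged on mean membrane DAB OD, immune cells on mean
whole-cell DAB OD, both with a ≥ convention at the threshold; stromal cells
are never positive. The threshold default of 0.2 (log10 OD) is the central
under-documented parameter of DAB positivity; it appears in the config, the
CLI and every report. "Viable" tumor cells are all detected tumor-class
cells — the pipeline has no necrosis class. TPS and CPS share the
tumor-cell denominator; CPS is capped at 100 by definition; ICS divides the
summed cell-polygon area of positive immune cells by the tumor annotation
area (a config switch substitutes DAB-positive pixel area for the
numerator). When no tumor cell is detected, TPS and CPS are reported as
undefined flags rather than raised errors, so "no tumor" remains a valid
pipeline outcome (CLI exit code 3). Scores print to one decimal in
human-readable output and at full precision in JSON.

## Agreement statistics

ICC defaults to two-way random effects, single rater, absolute agreement:
ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) from the two-way
ANOVA mean squares, with the F-test p-value (df n−1, (n−1)(k−1)) and the
standard Satterthwaite-df confidence interval. All six common variants are
selectable as point estimates; the report records which was used. A matrix
with zero variance across both cases and raters is an error ("ICC
undefined"); identical raters over varying cases yield ICC 1 with p = 0.
Interpretation bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9
excellent, boundaries taking the higher band.

Weighted kappa uses equal, i.e. linearly spaced, disagreement weights
v_ij = |i−j|/(K−1) (quadratic available), reducing to Cohen's kappa at
K = 2; with more than two raters the arithmetic mean over all pairs is
reported along with the per-pair values. Cutoff concordance maps scores to
ordinal categories by a ≥ convention and reports percent agreement. Paired
comparisons run Shapiro–Wilk on the differences and a two-sided Wilcoxon
signed-rank test: zero differences dropped, mid-ranks for ties, the exact
null for n ≤ 25 without ties and the tie-corrected normal approximation
otherwise; all-zero differences report p = 1.0 as "no difference". The
significance level is fixed at 0.05 and no multiple-testing correction is
applied. The human consensus score is the arithmetic rater mean.

## Synthetic material

The generator emulates H-DAB stained tissue at desk scale: a tile-aligned
mosaic (default 5×5 tiles of 256 µm at 0.5 µm/px) of eight tissue textures
plus bare glass, a simply connected random tumor blob (default 10 tiles,
0.66 mm²), and, inside the tumor region, individually placed cells with
complete ground truth. Tile alignment makes the true tumor area an exact
multiple of the tile area; the blob is kept simply connected because the
pipeline — by design — fills labelmap gaps, so enclosed non-tumor tiles in
the truth could never be recovered by a correct pipeline.

Cell placement is Poisson-disc-style dart throwing with minimum spacing
1.5× the mean nucleus radius, thinned to the requested densities: tumor
1400, immune 450, stromal 350 per mm². These densities keep roughly 80% of
nuclei non-touching, the regime the detection-quality targets assume —
touching pairs occur and exercise the watershed without dominating. Nuclei
are ellipses with class-dependent geometry and hematoxylin OD: tumor large
and pleomorphic (radius 5 ± 0.9 µm, aspect 1–2, OD 0.75), immune small and
round (2.8 ± 0.3 µm, aspect ≤ 1.2, OD 0.95), stromal elongated (3.2 ± 0.4
µm, aspect 2.5–4, OD 0.50), each with ±15% per-cell intensity jitter.
PD-L1-positive tumor cells receive a membranous DAB ring (OD 0.8) of width
equal to the pipeline's default membrane thickness at the true cell
boundary, so the compartment rule is testable end-to-end; positive immune
cells receive whole-cell DAB (OD 0.6). Gaussian OD noise (sd 0.02) is added
to both channels and the image is composed through the same Beer–Lambert
inversion the analysis uses, with white point (242, 242, 242).

Positive tumor cells are assigned by exact count (round(target·n)), and
positive immune cells greedily until their summed cell area best matches
the ICS target; unreachable targets (e.g. positive TPS with zero tumor
density) raise. The realized scores stored in the truth are computed from
the truth table by the same `compute_scores` used on pipeline output, so
truth is self-consistent by construction. All randomness derives from one
integer seed through named substreams (`SeedSequence([seed, key, ...])`),
so sub-generators are independently reproducible and identical seeds give
bit-identical slides.

Texture classes follow distinct generative statistics (adipose: sparse
large ring outlines; cartilage: isolated lacunae in a faint matrix;
epithelium: oriented nuclear bands; gland: nuclear rings around empty
lumina; immune: dense small round nuclei at 7000/mm²; muscle: oriented
fibers with aligned elongated nuclei; stroma: sparse elongated nuclei;
tumor: the mixed-cell field above), so blob-count densities order
immune > tumor > stroma.

**What passing on this material shows — and what it does not.** The
generator provides crisp nuclear boundaries, a stain basis identical to the
analysis basis, tile-pure tissue regions, no artifacts (folds, pen, carbon,
necrosis), no out-of-focus regions and no scanner-to-scanner color
variation. Passing the end-to-end panel therefore validates the geometry,
compartment logic, training plumbing and score arithmetic — not performance
on clinical slides, where staining variation, artifacts and tumor
heterogeneity dominate the error budget.

## Validation design and problem sizes

The test panel uses ten slides (two replicates of TPS targets {0, 5, 25,
60, 95}% with ICS 0–5%) of 1280 µm square at 0.5 µm/px (~900 tumor cells
per slide), scored with models trained on tiles and two slides from a
disjoint seed; recovery bands are ±10 points for TPS and CPS and ±3 for
ICS, with ≥ 80% cutoff-category concordance. Statistical routines are
checked against from-definition oracles (raw sum-of-squares ANOVA for ICC,
hand-computed kappa tables, the exact signed-rank null) and against an
independent implementation where one exists. These sizes keep the whole
suite within a coffee break on one CPU while leaving every stage
non-trivially exercised.

## Known limitations

* The default tile classifier is a texture-feature MLP, not a deep
  convolutional model; on real WSIs a CNN behind the same interface is the
  expected upgrade path.
* The classical nucleus detector under-segments deeply fused same-intensity
  nuclei; detection recall/precision ≈ 0.9–0.95 in the default synthetic
  regime, and missed cells are approximately random with respect to
  positivity, so score bias is small but not zero (ICS is mildly
  underestimated because clipped detected cells are slightly smaller than
  truth cells).
* Whole-slide pyramidal formats are supported only through in-memory RGB
  arrays and tiled TIFF/PNG; a pyramidal reader is a pluggable adapter, not
  a dependency.
* The DAB positivity threshold is a single global OD cutoff; no
  multi-intensity (1+/2+/3+) grading, and no IC% (positive fraction of
  immune cells) — ICS is an area ratio by definition.
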