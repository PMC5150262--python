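# Methods

## Readouts and segmentation

The screen's phenotype is junction assembly in a confluent epithelial
monolayer, read out per well as three percent-thresholded-area parameters:

* **E-cad** — fraction of pixels above threshold in the E-cadherin
  channel. The channel mixes background, diffuse cytoplasmic staining and
  a bright junctional ribbon; the threshold must sit above the cytoplasmic
  mode.
* **Jun-A** — thresholded F-actin restricted to the E-cad mask (the
  junctional actin pool).
* **Cyt-A** — thresholded F-actin outside both the E-cad mask and the
  nuclei (the cytoplasmic pool). Jun-A and Cyt-A partition the
  thresholded actin signal by construction.

Supporting measures: total F-actin intensity and percent area, nuclei
count (threshold + connected components with a minimum area, default
50 px; touching nuclei merge and count once), and a confluence QC flag.

**Thresholding.** The E-cad policy is a two-pass Otsu: pass one separates
background from signal; pass two, on above-background pixels, separates
cytoplasm from junction but is accepted only when the two classes it
produces are genuinely separated — Ashman's
D = |μ₁−μ₂| / √((σ₁²+σ₂²)/2) ≥ 4. Bisecting a single Gaussian mode yields
D ≈ 2.65, so a field without cytoplasmic staining keeps the pass-one
threshold instead of having its ribbon mode split in half; well-separated
cytoplasm/junction modes give far larger D. A fixed-percentile policy
(`percentile:P`) is available; the policy and thresholds used are recorded
in every output row. The actin-pool threshold is Otsu accepted only when
its sub-threshold class is background-dark (mean below the camera floor);
in a fully confluent field there is no background mode, Otsu would split
cytoplasmic from junctional actin and zero Cyt-A, so the fixed floor (4% of
the dtype range) is used there.

**Confluence QC.** Coverage is percent area above the same fixed floor;
wells below `min_coverage` (default 90%) are flagged, never deleted, so
replicate medians degrade gracefully and an audit trail remains.

**Junctional protein coverage.** For an arbitrary protein channel, the
E-cad mask is dilated (default radius 2 px) and the protein image is
thresholded with a caller-supplied *global* threshold shared across all
wells of an experiment. A per-image threshold would adapt away exactly the
between-condition intensity differences this measure exists to detect, so
its absence is an error rather than a default.

Masks are binary pixel sets, row-major, origin top-left; no sub-pixel
geometry. Junction shape/length/continuity metrics and per-cell
segmentation are out of scope.

## Screen statistics

Z-scores are computed per plate against control wells, by default the
untransfected junction-induced positive controls (samples are
junction-induced, so deviations from normal assembly are the signal):
`z = (x − center) / scale` with robust center/scale (median, MAD × 1.4826)
by default because screen data are typically non-Gaussian; moment mode
(mean, SD, ddof = 0) is retained and recorded. Constant controls flag the
plate and leave Z missing — never ±∞. Per-gene final scores are medians
over QC-passing replicates; candidates satisfy |median z| > 1.65 for any
parameter, strictly (a median of exactly 1.65 is not a candidate).
Validation calls on four single oligos: ≥ 2 above +cutoff and not
ambiguous → validated_up (mirrored down); ≥ 2 above and ≥ 2 below →
ambiguous. The validation cutoff is a separate configurable (default 1.0)
because validation-screen amplitudes are smaller than primary-screen ones.

Correlations are Pearson R with the two-sided slope test (the F-test on a
simple regression slope equals the squared-t test and gives the same
p-value); constant columns report missing R. Normality uses Shapiro–Wilk
on raw data and on a three-parameter shifted log, log(x − c), with the
shift chosen by bounded minimization of |sample skewness| — the standard
skew-correction when the location offset of a log-normal candidate is
unknown.

## Phenotypic clustering

Candidates are points in ℝ³ (median Z for E-cad, Jun-A, Cyt-A).
Mahalanobis distance uses the pooled sample covariance of the candidate
matrix with a ridge proportional to each variance (1e-6 of it) — this
regularization keeps distances exactly equivariant under per-axis
rescaling, which a trace-scaled ridge would break. Similarity is
s = exp(−d²/2σ²) with σ = 1. The mutual kNN graph (k = 30; edge kept only
when each endpoint ranks in the other's top k, ranking ties broken by
index) feeds the symmetric normalized Laplacian
L_sym = I − D^(−1/2) W D^(−1/2); its bottom-k eigenvectors, row-normalized
(Ng–Jordan–Weiss), are clustered by k-means with a fixed seed and 50
restarts. The random-walk variant (generalized eigenproblem L v = λ D v,
no row normalization) is available as `laplacian="rw"`. When the graph has
more connected components than requested clusters, each component becomes
its own cluster with a warning. Hierarchical clustering uses average
linkage on the distance matrix; plain k-means under Mahalanobis runs in
the whitened space (equivalent by construction). Labels are canonicalized
by decreasing cluster size (ties by smallest member index), which makes
the *partition* permutation-equivariant; the numbering itself can permute
when sizes tie.

Silhouettes are computed from the clustering's own distance matrix:
s_i = (b_i − a_i)/max(a_i, b_i); members of singleton clusters score 0 (the
common convention). Model selection over the (method × distance × k) grid
uses fewest negative silhouette values as the primary criterion —
silhouettes are the validity measure, and a negative value marks a likely
misclassification — with ties broken by highest mean silhouette, then
smallest k.

## Commute-time-kernel cluster validation

The PPI network over candidates and their background interacting
neighbours is converted, per connected component, into
K = L⁺ (Moore–Penrose pseudoinverse of the combinatorial Laplacian
L = D − A, via `scipy.linalg.pinvh`); cross-component entries are 0. K is
symmetric PSD with zero row sums per component, and its entries act as
random-walk similarities. The CK-max score of a partition sums, for every
candidate protein, the maximum kernel similarity to another protein in the
same cluster; singletons and proteins absent from the network contribute 0
(absences are counted in a coverage report). Background nodes shape the
kernel but are never scored. The null preserves cluster count and sizes
and shuffles membership uniformly; the right-tailed empirical p-value uses
the +1 correction, p = (1 + #{null ≥ obs}) / (1 + n_random), with
n_random = 10,000 by default (a warning is emitted when fewer distinct
partitions exist than requested). A kernel-density summary of the null
with the observed score is exported for plotting.

## Function enrichment

Annotations map genes to one or more of 13 curated actin-function classes.
The vocabulary ships as a YAML data file (polymerization, bundling,
capping, severing/depolymerization, cross-linking, branching, trafficking,
contraction, adhesion regulation, filament stabilization, nucleation,
scaffolding, motor activity) and is user-replaceable; class names are
data, not code. Two layers per function × cluster cell: share_of_class
(genes in the cluster with the function over all annotated genes carrying
it — columns sum to 1 when every annotated gene is clustered) and
share_of_cluster (annotation instances of the function over all instances
in the cluster; multi-function genes count once per function).
Enrichment is share_of_class ≥ 0.25, inclusive. The profile's rows and
columns are ordered by average-linkage hierarchical clustering on
Euclidean distances for heat-map rendering.

## Synthetic data: what it emulates and what it does not

**Monolayer images.** Cells are a Lloyd-relaxed Voronoi tessellation
(epithelial monolayers are near-centroidal; relaxation also keeps
neighbouring nuclei apart). Junctions are a ~3 px ribbon along boundaries
between retained cells; `junction_coverage` and `actin_junction_coverage`
drop whole cell-pair boundary segments to emulate incomplete junction
assembly — the screen's actual phenotype axis, and the reason percent-area
readouts respond to these parameters rather than to brightness. The
cytoplasmic actin pool is a smoothed random field, nuclei are ellipses,
noise is additive Gaussian (read noise) clipped to the bit depth; Poisson
shot noise is omitted because the segmentation is threshold-based, not
noise-statistics-based. `gap_fraction` is the fraction of monolayer *area*
opened as holes (cells are deleted until that area is reached, and cells
at free edges retract by `gap_margin` = 3 px) — area semantics because the
confluence QC is area-based. Not emulated: photorealistic optics, 3-D
stacks, cell-shape phenotypes, junction continuity defects below the
segment scale. Passing segmentation tests therefore shows the mask algebra
and threshold policies are correct on images with the assumed intensity
structure, not that they are robust to arbitrary microscopy artefacts.

**Screen tables.** Raw well values are
baseline + plate_shift + z·(control SD) + noise, with junction-induced
positive controls and no-junction negative controls on every plate.
Positive-control draws are standardized to exact per-plate mean/SD so the
noiseless limit recovers planted Z centers exactly under moment
normalization — which turns hit-selection consistency into an exact check.
The default study condition plants nine clusters at centers on a ±4 grid
in Z space (pairwise separation ≥ 4 control SDs) with within-cluster SD
0.5 and 156 genes; this is "moderate separation" in the sense that raw
values overlap across plates (plate shift 5) yet normalized phenotypes
are resolvable, the regime a successful screen operates in. Plate effects
are additive only.

**Networks and annotations.** PPI graphs are stochastic block models over
the planted clusters (defaults p_within = 0.3, p_between = 0.01) plus
uniformly attached background nodes; annotations give each gene one or
more classes with a configurable planted over-represented class per
cluster. Real interactomes have hubs, degree heterogeneity and study bias
that an SBM lacks; calibration results on these graphs bound the test's
behaviour under its own null, not under literature bias.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeds carried in
  the specs/configs; generators are bit-identical under a fixed seed, and
  a full pipeline rerun with the same config is byte-identical (manifests
  record config hashes and row counts, never timestamps).
* Kernel PSD tolerance 1e-8; pseudoinverse axioms hold to ~1e-13 in
  practice. Degenerate inputs (constant images, constant controls, empty
  masks, singleton clusters, k = 1) return defined values with warnings
  rather than NaN surprises, as documented per function.
* Problem sizes in tests and the acceptance script (156-gene screens,
  ≤50-node random graphs, 1,000-10,000 randomizations, 24-gene rendered
  tiny screen) were chosen to exercise every stage at the screen's
  published scale or a faithful reduction of it.

## Known limitations

* The E-cad bimodality gate (D ≥ 4) assumes cytoplasm and junction modes
  are well separated relative to noise; heavily blurred real images may
  fall between the two policies and should use the percentile policy with
  a calibrated P.
* CK-max has no analytic null; inference is purely empirical, so the
  smallest attainable p is 1/(1 + n_random).
* Cluster numbering is stable only up to cluster-size ties; compare
  partitions, not label values, across runs with different input orders.
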