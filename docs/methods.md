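# Methods

This note documents the models and procedures implemented in `gliospat`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions used throughout.

## Data model

A **cell table** holds one row per segmented cell: centroid coordinates in
μm, a case id, a region id (regions partition cells within cases), a region
class (tumor `edge` or `core`), a population label drawn from a declared
finite set, and per-marker mean intensities. Marker normalization divides
each marker by its own 99th percentile over all cells and clips at 1, so a
marker whose 99th percentile is 0 maps to all-zeros and already-normalized
data whose 99th percentile is exactly 1 passes through unchanged.

**Marker rasters** are single-channel non-negative grids at a configurable
μm-per-pixel scale (default 1). Pixel (i, j) has its center at
`origin + ((j+0.5)·scale, (i+0.5)·scale)`; rows index y, columns index x.
All window membership is decided by pixel centers.

**Cell graphs** come in two modes. `knn` (default k = 6) computes the
directed k-nearest-neighbor relation by Euclidean distance and symmetrizes
by edge union, so every node in a region larger than k has degree ≥ k;
distance ties are broken by lexicographic cell id for determinism. The
`contact` mode approximates touching cells by a centroid-distance threshold
(default 15 μm, configurable) because segmentation masks are outside the
package's scope; the true mask-adjacency rule used upstream of such data is
generally unknowable from centroids, and results that depend on contact
neighborhoods (Rao entropy) should be read with that approximation in mind.

## Permutation null

All cell-level enrichment statistics share one null model: positions fixed,
population labels uniformly permuted within the region (default 300 draws).
This conditions on both the spatial point pattern and the abundance
composition, so a positive/negative difference is attributable to how
labels sit on the pattern, not to how many cells there are. The null is
summarized by its mean (the "expected by chance" value) and the null SD is
kept for diagnostics. Each (region, statistic) pair has an independent RNG
stream derived from the master seed plus CRC32 hashes of the region id and
statistic name; internally cells are processed in canonical cell-id order,
so results are invariant to row order and bitwise reproducible for a fixed
seed. Undefined matrix entries (empty populations, edgeless populations, a
lone same-population cell) propagate as missing values, never as zeros.

Cross-region inference uses a one-sample Wilcoxon signed-rank test of the
per-region differences against zero, grouped by region class, with
Benjamini-Hochberg correction over all population pairs tested within a
group. Each region contributes one value, unweighted — cases with more
regions are not up-weighted. All-zero difference vectors are reported as
p = 1 with a degeneracy flag rather than an error.

## Topology descriptors

Per-population clustering is the mean local clustering coefficient
(triangles over possible triangles; degree < 2 contributes 0) of the
population's vertex-induced subgraph of the region's 6-NN graph, computed
with a sparse-matrix triangle count; populations with fewer than 3 members
are reported as 0 and flagged. The abundance-corrected value subtracts the
label-permutation mean on the fixed graph. Assortativity is Newman's
discrete coefficient from the edge mixing matrix; because a per-population
decomposition of that coefficient is not canonical, both the whole-graph
value and the per-label assortative excess `e_ii − a_i·b_i` are reported.

## Microenvironment quantification

* **Rao's quadratic entropy**: `Q = Σᵢⱼ pᵢpⱼ d(i,j)` over the cell plus its
  contact neighbors, with uniform weights `pᵢ = 1/m` and Euclidean distance
  between normalized marker vectors. Isolated cells return 0, flagged.
* **Window expression**: mean of the raster pixels whose centers fall in a
  40-μm axis-aligned square centered on the cell (a disc of 40-μm diameter
  is available via `shape="disc"`; the square is the default and the two
  give very similar values on smooth fields). Windows are clipped at raster
  borders; a window holding no pixel centers yields a flagged missing value.
* **Cross-PCF**: the count of population-pair point pairs within 20 μm,
  normalized by `n_a·n_b`, against the same label-permutation null (the pair
  set is precomputed once since positions never move). The empirical
  two-sided p uses the add-one correction `(1 + #extreme)/(n_perm + 1)`.
* **Vascular classes**: distance to the nearest vascular cell classifies
  cells as `vascular` (≤ near, default 0 μm — i.e. coincident/contact),
  `perivascular` (≤ far, default 10 μm) or `infiltrated` (beyond 10 μm).
  Both thresholds are configuration keys.

Group comparisons of per-cell environment values use a linear mixed model
with random intercepts for case and for region nested within case (REML,
statsmodels `MixedLM`), with the family of factor-level contrasts adjusted
by Holm-Šídák. If every case holds a single region the region term is
dropped (flagged); on non-convergence the comparison falls back to
Mann-Whitney tests on region means, flagged as such. Simulations in the
test suite confirm the nominal type-I rate (≤ 0.07 at α = 0.05 over 200
null simulations) and ≥ 90% power for a 1-SD shift at 10 cases × 3 regions
× 50 cells.

## Spot-level niches and survival

Spot datasets are AnnData objects on an axial hexagonal grid. QC removes
spots with total counts strictly below 1000 and genes whose names start
with a mitochondrial prefix (default `MT-`); remaining counts are scaled
per spot to the median pre-scaling total (scanpy's default target) and
log(1+x)-transformed. The normalization target is a package choice — any
fixed target gives identical downstream rank statistics.

Signature scoring is a per-spot hypergeometric upper-tail test of the
overlap between a gene set and the spot's top 5% expressed genes (ties
broken by gene name), reported as −log10 p. The top-fraction selection rule
is a documented stand-in for tool-specific defaults used in comparable
pipelines; the fraction is a parameter.

Myeloid environments are discovered by k-means (k = 5 by default, 10
restarts, fixed seed) on abundances standardized to zero mean and unit
variance per population; labels are renumbered by descending cluster size
so the labeling is deterministic. k-means was chosen over graph-based
community detection for determinism and because the number of environments
is an explicit input; a batch field is accepted but ignored with a warning
(the generators produce a single batch). Environment connectivity connects
each spot to its ≤ 6 axial hex neighbors and reports row-normalized
adjacency proportions between environment labels.

Non-myeloid signal is isolated by discarding genes whose reference-signature
SD across myeloid populations exceeds 0.1 (counts scale); the retained genes
are tested per environment with one-vs-rest Wilcoxon rank-sum tests, keeping
genes with raw p < 0.01 and fold ≥ 1.5, the fold computed on
expm1-backtransformed group means with a 1e-9 pseudocount guarding the
division.

Survival association fits one univariate Cox proportional-hazards model per
environment proportion (lifelines partial likelihood), with the covariate
expressed in percentage points so hazard ratios read "per percentage point
of environment abundance"; p-values are Holm-Šídák adjusted across
environments. Kaplan-Meier comparisons split samples at the median
proportion (top 50% vs rest); a mean split is available by flag. Note the
compositional caveat: proportions sum to 1, so univariate (marginal)
estimates absorb part of any opposite-signed effect on other components —
with a symmetric simplex distribution the cross-component leakage is
`−1/(k−1)` of each omitted effect. The package estimates the marginal
association, which is also what the simulation checks target.

## Synthetic generators

`simulate_region` emulates a 1 mm² imaging region: vascular skeletons as
random line segments rendered into cell chains (~8 μm spacing), a hypoxia
field built from the vessel distance transform (`d/(d+L)`, L = 150 μm)
blended with low-pass Gaussian noise, fibrinogen as a vessel-proximal decay
plus Gaussian leak blobs at a random half of the segments, and populations
placed by CSR (Poisson counts), Thomas processes (Poisson parents at
20/mm², Gaussian offspring dispersion σ = 30 μm), vessel-distance-decaying
acceptance, or hypoxia-weighted acceptance (`∝ exp(4·hypoxia)`). Marker
intensities are population archetypes (0.8 vs 0.1) plus Gaussian noise
(SD 0.1) truncated at zero.

`simulate_spots` plants contiguous vertical bands of 5 environments on a
25 × 20 hex grid, each environment dominated by a rotating pair of myeloid
populations (abundance noise SD = 0.1 × the abundance scale), and assembles
counts as negative-binomial draws (gamma-Poisson, dispersion 0.5) around
signature-weighted rates with 3-fold boosts of 8 planted non-myeloid genes
per environment, scaled to log-normal library sizes (median ≈ 5000).

`simulate_cohort` draws environment proportions from a symmetric
Dirichlet(2), event times from an exponential with rate
`λ₀·exp(Σ βₖ·100·propₖ)` (λ₀ = 1/12 per month), and independent uniform
censoring whose upper bound is bisected so the realized censored fraction
matches the request.

What the generators do **not** emulate: cell morphology and segmentation
error, marker spillover, spatially varying cell density gradients beyond
vessels/hypoxia, multi-batch effects, spot bleed-over between neighboring
spots, and non-proportional hazards. Passing tests therefore demonstrate
the statistics' calibration and recovery behavior under the assumed data
model, not robustness to those real-data artifacts.

## Problem sizes and numerics

The test suite and the acceptance script run at sizes chosen to make the
Monte-Carlo assertions stable on a single CPU: 20 × 2000-cell CSR regions
(300 permutations) for null calibration, 45 × 20 small regions for the
group-test error rate, 50 seeds for Thomas recovery, 200 simulations for
the mixed-model and family-wise error rates, 500-spot datasets, and
400-sample cohorts. Oracle comparisons are exact to 1e-9. Floating-point
output in the CLI uses a fixed `%.10g` format so identical seeds yield
byte-identical files. Seeds derived internally stay below 2³¹.

## Known limitations

* Contact graphs are centroid-threshold approximations (no masks).
* The per-spot gene-selection rule behind signature scoring, and the exact
  square-vs-disc window shape, are documented conventions rather than
  reproductions of any specific upstream tool; both are configurable.
* Univariate Cox estimates are marginal associations of compositional
  covariates (see above).
* The group-level Wilcoxon tests treat regions as exchangeable within edge
  or core; with very unbalanced region counts per case a case-level
  aggregation may be preferable.
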