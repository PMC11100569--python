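# gliospat

Spatial statistics for labeled cell point patterns in tumor tissue, built
around the question of how myeloid cells organize in the glioblastoma
microenvironment: do populations cluster with their own kind, which
microenvironments (hypoxia, fibrinogen leak, vasculature) do they occupy,
which spot-level "myeloid environments" exist in spatial transcriptomics,
and do those environments associate with patient survival?

The package is aimed at analysts working with multiplexed imaging
(imaging mass cytometry or similar segmented single-cell tables with μm
coordinates and population labels) and Visium-style hex-grid spot data with
cell-type abundances from an upstream deconvolution.

## The statistics at the core

All cell-level inference runs against a **label-permutation null**: cell
positions stay fixed and population labels are reshuffled uniformly within
each region (300 draws by default), so per-population abundances are
conserved exactly. For a statistic *T* the package reports
`diff = T(observed) − mean(T(permuted))`:

* **Distance enrichment** — `T(i, j)` = mean over population-*i* cells of the
  distance to the nearest population-*j* cell. `diff < 0`: closer than chance.
* **Interaction enrichment** — on the 6-nearest-neighbor graph,
  `T(i, j)` = fraction of population-*i* edge endpoints landing on
  population *j*. `diff > 0`: more contact than abundances predict.
* **Abundance-corrected clustering** — mean local clustering coefficient of
  each population's induced subgraph, minus its permutation-null mean.
* **Assortativity** — Newman's discrete coefficient
  `r = (Σᵢ eᵢᵢ − Σᵢ aᵢbᵢ) / (1 − Σᵢ aᵢbᵢ)` on the label mixing matrix.
* **Cross-PCF** — co-occurrence of two populations within 20 μm vs the null,
  with an add-one empirical p-value.
* **Rao's quadratic entropy** — `Q = Σᵢⱼ pᵢpⱼ d(i, j)` over a cell's contact
  neighborhood (uniform weights, Euclidean phenotype distance).
* **Microenvironment windows** — mean raster intensity (hypoxia, fibrinogen)
  in a 40-μm window centered on each cell; vascular association classes at a
  10-μm infiltration threshold.

Cross-region comparisons use one-sample Wilcoxon signed-rank tests of the
diffs with Benjamini-Hochberg correction; per-cell environment values are
compared with linear mixed models (cells ⊂ regions ⊂ cases, Holm-Šídák).
Spot-level niches come from k-means on standardized abundances (k = 5),
their marker genes from one-vs-rest Wilcoxon tests (P < 0.01, ≥1.5-fold) on
non-myeloid genes, and survival association from univariate Cox models per
environment proportion (hazard ratios per percentage point, Holm-Šídák,
top-50% Kaplan-Meier split).

Everything is exercised end to end on synthetic tissue from the
`gliospat.simulate` generators (Thomas-process clustering, vascular
skeletons, hypoxia/fibrinogen rasters, planted spot environments, cohorts
with log-linear hazards), so no external data is required.

## Worked example

```python
import gliospat as gs

# a 2-case x 2-region synthetic study
cells, rasters = gs.simulate_study(seed=4, n_cases=2, regions_per_case=2,
                                   base_config=gs.TissueConfig(width_um=400,
                                                               height_um=400))
res = gs.SpatialEnrichment(cells, statistic="distance", n_perm=300).fit(seed=4)
print(res.summary().query("pop_i == pop_j == 'PopA'")
      [["group", "mean_diff", "p", "p_adj"]])
```

```
   group  mean_diff    p     p_adj
0   core  -3.948428  0.5  0.533333
16  edge  -4.621973  0.5  0.500000
```

`PopA` is placed as a Thomas cluster process, so its same-population mean
nearest-distance sits ~4 μm below the permutation-null expectation
in both edge and core regions (negative `mean_diff` = tighter homotypic
clustering than chance). With only two regions per group the signed-rank
test cannot reach significance — the per-region diffs, not the p-values,
carry the signal at this size.

```python
ds, truth = gs.simulate_spots(gs.SpotSimConfig(seed=6))
qc = gs.qc_normalize(ds)                      # <1000-count spots, MT- genes out
niches = gs.NicheModel(qc, k=5, signatures=truth["signatures"]).fit(seed=0)
print(niches.summary())
```

```
   environment  n_spots  self_connectivity  n_marker_genes
0            0      101           0.843003               8
1            1      100           0.927911               8
2            2      100           0.913124               8
3            3      100           0.865517               8
4            4       99           0.853659               8
```

Five environments are recovered, each spatially contiguous (self-adjacency
0.84–0.93 on the hex spot graph) and each carrying its 8 planted
non-myeloid marker genes.

The same stages are available from the shell (`gliospat simulate`,
`gliospat ingest`, `gliospat spatial-stats`, `gliospat topology`,
`gliospat environment`, `gliospat vascular`, `gliospat niches`,
`gliospat survive`); every stage is byte-reproducible under a fixed
`--seed`.

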