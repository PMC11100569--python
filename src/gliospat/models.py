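"""Model-style entry points: build a model from data, ``fit()``, inspect results.

Each class wraps one analysis stage as a statsmodels-like pair: the model
holds the data and the analysis parameters, ``fit`` runs the computation
(all randomness through an explicit seed) and returns a results object with
the estimates, their null/uncertainty context and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import niches as nch
from . import permutation as perm
from . import topology as topo
from .environment import NestedCompareResult, nested_compare
from .niches import SpotDataset, SurvivalCohort
from .tissue import CellTable, build_graph

__all__ = [
    "SpatialEnrichment",
    "SpatialEnrichmentResults",
    "TopologyAnalysis",
    "TopologyResults",
    "NestedComparison",
    "NicheModel",
    "NicheResults",
    "SurvivalAssociation",
    "SurvivalResults",
]


# ---------------------------------------------------------------------------
# spatial enrichment
# ---------------------------------------------------------------------------

@dataclass
class SpatialEnrichmentResults:
    region_results: list[perm.EnrichmentResult]
    group_table: pd.DataFrame | None
    statistic: str
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.region_results],
                         ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Per-group mean differences with Wilcoxon/BH inference."""
        if self.group_table is None:
            return (self.to_frame()
                    .groupby(["pop_i", "pop_j"], as_index=False)["diff"].mean())
        return self.group_table


class SpatialEnrichment:
    """Permutation-null enrichment of a spatial statistic across regions.

    statistic ``distance``: mean nearest-distance between population pairs;
    ``interaction``: edge-endpoint interaction proportions on the k-NN graph.
    """

    def __init__(self, cells: CellTable, statistic: str = "distance", k: int = 6,
                 n_perm: int = perm.DEFAULT_N_PERM):
        if statistic not in ("distance", "interaction"):
            raise ValueError(f"unknown statistic {statistic!r}")
        self.cells = cells
        self.statistic = statistic
        self.k = k
        self.n_perm = n_perm

    def fit(self, seed: int = 0, group: bool = True) -> SpatialEnrichmentResults:
        results = []
        for (case_id, region_id), region in self.cells.iter_regions():
            if self.statistic == "distance":
                res = perm.distance_enrichment(region, n_perm=self.n_perm, seed=seed)
            else:
                graph = build_graph(region, mode="knn", k=self.k)
                res = perm.interaction_enrichment(region, graph,
                                                  n_perm=self.n_perm, seed=seed)
            results.append(res)
        table = None
        if group:
            groups = [r.region_class or "all" for r in results]
            enough = pd.Series(groups).value_counts()
            if (enough >= 2).any():
                keep = [r for r, g in zip(results, groups) if enough[g] >= 2]
                table = perm.group_test(keep)
        return SpatialEnrichmentResults(results, table, self.statistic,
                                        self.n_perm, seed)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class TopologyResults:
    region_results: list[topo.TopologyResult]
    k: int
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.region_results],
                         ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Mean raw/corrected clustering and assortativity per population/group."""
        df = self.to_frame()
        return (df.groupby(["region_class", "population"], as_index=False)
                  .agg(observed=("observed", "mean"),
                       corrected=("corrected", "mean"),
                       assortative_excess=("assortative_excess", "mean"),
                       assortativity_graph=("assortativity_graph", "mean")))


class TopologyAnalysis:
    """Clustering-coefficient and assortativity descriptors on k-NN graphs."""

    def __init__(self, cells: CellTable, k: int = 6,
                 n_perm: int = perm.DEFAULT_N_PERM):
        self.cells = cells
        self.k = k
        self.n_perm = n_perm

    def fit(self, seed: int = 0) -> TopologyResults:
        results = []
        for (case_id, region_id), region in self.cells.iter_regions():
            graph = build_graph(region, mode="knn", k=self.k)
            results.append(topo.region_topology(
                graph, region.labels, populations=region.populations,
                n_perm=self.n_perm, seed=seed, region_id=region_id,
                region_class=region.df["region_class"].iloc[0]))
        return TopologyResults(results, self.k, self.n_perm, seed)


# ---------------------------------------------------------------------------
# nested mixed-model comparison
# ---------------------------------------------------------------------------

class NestedComparison:
    """Mixed-model comparison of a per-cell value between factor levels.

    Cells nest within regions within cases; ``fit`` returns the
    Holm-Šídák-adjusted factor contrasts.
    """

    def __init__(self, data: pd.DataFrame, value: str, factor: str,
                 case: str = "case_id", region: str = "region_id"):
        self.data = data
        self.value = value
        self.factor = factor
        self.case = case
        self.region = region

    @classmethod
    def from_cells(cls, cells: CellTable, values: np.ndarray, factor: str = "population"):
        df = cells.df[["case_id", "region_id", factor]].copy()
        df["value"] = np.asarray(values, float)
        return cls(df, "value", factor)

    def fit(self) -> NestedCompareResult:
        return nested_compare(self.data, value=self.value, factor=self.factor,
                              case=self.case, region=self.region)


# ---------------------------------------------------------------------------
# niches
# ---------------------------------------------------------------------------

@dataclass
class NicheResults:
    labels: np.ndarray
    connectivity: pd.DataFrame
    markers: dict[int, pd.DataFrame]
    nonmyeloid_genes: list[str] | None
    k: int
    seed: int

    def summary(self) -> pd.DataFrame:
        sizes = pd.Series(self.labels).value_counts().sort_index()
        diag = np.diag(self.connectivity.to_numpy())
        return pd.DataFrame({
            "environment": sizes.index,
            "n_spots": sizes.to_numpy(),
            "self_connectivity": diag,
            "n_marker_genes": [len(self.markers.get(int(e), ()))
                               for e in sizes.index],
        })


class NicheModel:
    """Myeloid-environment discovery on a QC'd spot dataset.

    Clusters standardized abundances into ``k`` environments (k-means),
    measures hex-grid connectivity between them, and extracts per-environment
    non-myeloid marker genes when reference signatures are supplied.
    """

    def __init__(self, spots: SpotDataset, k: int = 5,
                 signatures: pd.DataFrame | None = None,
                 sd_threshold: float = 0.1, p_max: float = 0.01,
                 min_fold: float = 1.5):
        self.spots = spots
        self.k = k
        self.signatures = signatures
        self.sd_threshold = sd_threshold
        self.p_max = p_max
        self.min_fold = min_fold

    def fit(self, seed: int = 0) -> NicheResults:
        labels = nch.cluster_environments(self.spots.abundances, k=self.k, seed=seed)
        self.spots.set_environment(labels)
        conn = nch.environment_connectivity(self.spots)
        markers: dict[int, pd.DataFrame] = {}
        nonmyeloid = None
        if self.signatures is not None:
            sig = self.signatures.loc[:, [g for g in self.signatures.columns
                                          if g in set(self.spots.genes)]]
            nonmyeloid, _ = nch.nonmyeloid_signature(sig, self.sd_threshold)
            if nonmyeloid:
                markers = nch.environment_markers(self.spots, nonmyeloid,
                                                  p_max=self.p_max,
                                                  min_fold=self.min_fold)
        return NicheResults(labels, conn, markers, nonmyeloid, self.k, seed)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResults:
    table: pd.DataFrame
    km: dict
    split: str
    cohort: SurvivalCohort = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        return self.table[["environment", "hr", "log_hr", "se", "p", "p_adj"]]

    def plot_km(self, environment: str, ax=None):
        """Kaplan-Meier curves for the high/low split of one environment."""
        from lifelines import KaplanMeierFitter
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        info = self.km[environment]
        df = self.cohort.df
        for name, mask in (("high", info["high_mask"]), ("low", ~info["high_mask"])):
            kmf = KaplanMeierFitter()
            kmf.fit(df.loc[mask, "time"], df.loc[mask, "event"],
                    label=f"{environment} {name}")
            kmf.plot_survival_function(ax=ax)
        return ax


class SurvivalAssociation:
    """Univariate Cox association of environment proportions with survival."""

    def __init__(self, cohort: SurvivalCohort, split: str = "median",
                 scale_percent: bool = True):
        if split not in ("median", "mean"):
            raise ValueError("split must be 'median' or 'mean'")
        self.cohort = cohort
        self.split = split
        self.scale_percent = scale_percent

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, env_cols: list[str] | None = None,
                       **kw) -> "SurvivalAssociation":
        return cls(SurvivalCohort(df, env_cols=env_cols or []), **kw)

    def fit(self) -> SurvivalResults:
        table, km = nch.survival_association(self.cohort, split=self.split,
                                             scale_percent=self.scale_percent)
        return SurvivalResults(table, km, self.split, self.cohort)
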