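"""Population-level network descriptors on spatial cell graphs.

Clustering coefficients are computed per population on the vertex-induced
subgraph of that population within the region's six-nearest-neighbor graph,
then corrected for abundance by subtracting the mean of the same statistic
under random label permutations.  Assortativity is Newman's discrete
attribute assortativity over the population label, with an additional
per-label decomposition (e_ii − a_i·b_i) since whole-graph assortativity has
no canonical per-population split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .permutation import DEFAULT_N_PERM, permute_labels, region_rng
from .tissue import CellGraph

__all__ = [
    "TopologyResult",
    "population_clustering",
    "corrected_clustering",
    "label_assortativity",
    "per_population_assortativity",
    "region_topology",
]


def _local_clustering_mean(adj: sparse.csr_matrix, mask: np.ndarray) -> float:
    """Mean local clustering coefficient of the induced subgraph on ``mask``.

    Nodes of induced degree < 2 contribute 0, matching the convention of
    averaging the per-node coefficient over all subgraph nodes.
    """
    sub = adj[mask][:, mask].astype(np.int64)
    deg = np.asarray(sub.sum(axis=1)).ravel()
    # diagonal of A^3 counts 2 * triangles through each node
    tri2 = np.asarray((sub @ sub).multiply(sub).sum(axis=1)).ravel()
    possible = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(possible > 0, tri2 / possible, 0.0)
    return float(local.mean()) if len(local) else 0.0


def population_clustering(graph: CellGraph, labels: np.ndarray, population: str) -> float:
    """Average clustering coefficient of one population's induced subgraph."""
    labels = np.asarray(labels, dtype=str)
    mask = labels == population
    if not mask.any():
        raise ValueError(f"population {population!r} absent from graph")
    if mask.sum() < 3:
        warnings.warn(f"population {population!r} has < 3 members; clustering "
                      "coefficient reported as 0", stacklevel=2)
        return 0.0
    return _local_clustering_mean(graph.adjacency(), mask)


def corrected_clustering(graph: CellGraph, labels: np.ndarray,
                         populations: list[str] | None = None,
                         n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                         region_id: str = "") -> pd.DataFrame:
    """Abundance-corrected clustering: observed − permutation-null mean.

    The graph is fixed; labels shuffle.  Positive values mean the population
    clusters more densely than its abundance alone predicts.  Populations
    with < 3 members are undefined (NaN, flagged).
    """
    from .permutation import canonical_order as _canon

    labels = np.asarray(labels, dtype=str)
    pops = populations if populations is not None else sorted(set(labels))
    # canonical cell-id order so the null stream is row-order invariant
    order, rank = _canon(graph.nodes)
    labels = labels[order]
    n = graph.n_nodes
    if graph.n_edges:
        e = rank[graph.edges]
        data = np.ones(2 * len(e), dtype=np.int8)
        adj = sparse.coo_matrix((data, (np.r_[e[:, 0], e[:, 1]],
                                        np.r_[e[:, 1], e[:, 0]])), shape=(n, n)).tocsr()
    else:
        adj = sparse.csr_matrix((n, n), dtype=np.int8)
    counts = {p: int((labels == p).sum()) for p in pops}
    observed = {}
    for p in pops:
        observed[p] = (_local_clustering_mean(adj, labels == p)
                       if counts[p] >= 3 else np.nan)
    rng = region_rng(seed, region_id, "clustering")
    draws = np.full((n_perm, len(pops)), np.nan)
    for t in range(n_perm):
        perm = permute_labels(labels, rng)
        for pi, p in enumerate(pops):
            if counts[p] >= 3:
                draws[t, pi] = _local_clustering_mean(adj, perm == p)
    null_mean = np.nanmean(draws, axis=0)
    null_sd = np.nanstd(draws, axis=0, ddof=1) if n_perm > 1 else np.zeros(len(pops))
    obs = np.array([observed[p] for p in pops])
    return pd.DataFrame({
        "population": pops,
        "n_cells": [counts[p] for p in pops],
        "observed": obs,
        "expected": null_mean,
        "null_sd": null_sd,
        "corrected": obs - null_mean,
        "defined": [counts[p] >= 3 for p in pops],
    })


def _mixing_matrix(graph: CellGraph, codes: np.ndarray, n_pop: int) -> np.ndarray:
    """Symmetric edge mixing matrix e (fractions over directed edge ends)."""
    e = np.zeros((n_pop, n_pop))
    if graph.n_edges:
        cu, cv = codes[graph.edges[:, 0]], codes[graph.edges[:, 1]]
        np.add.at(e, (cu, cv), 1.0)
        np.add.at(e, (cv, cu), 1.0)
        e /= e.sum()
    return e


def label_assortativity(graph: CellGraph, labels: np.ndarray,
                        populations: list[str] | None = None) -> float:
    """Newman's discrete assortativity of the population label.

    r = (Σ e_ii − Σ a_i b_i) / (1 − Σ a_i b_i) from the edge mixing matrix;
    1 for perfectly assortative labelings, negative when edges preferentially
    join different populations.  Undefined (NaN) for single-label graphs.
    """
    labels = np.asarray(labels, dtype=str)
    if graph.n_edges == 0:
        raise ValueError("assortativity needs at least one edge")
    pops = populations if populations is not None else sorted(set(labels))
    lut = {p: i for i, p in enumerate(pops)}
    codes = np.array([lut[l] for l in labels], dtype=np.intp)
    e = _mixing_matrix(graph, codes, len(pops))
    a, b = e.sum(axis=1), e.sum(axis=0)
    denom = 1.0 - float(a @ b)
    if denom == 0.0:
        warnings.warn("single population on all edges; assortativity undefined",
                      stacklevel=2)
        return np.nan
    return (float(np.trace(e)) - float(a @ b)) / denom


def per_population_assortativity(graph: CellGraph, labels: np.ndarray,
                                 populations: list[str] | None = None) -> pd.Series:
    """Per-label assortative excess e_ii − a_i·b_i.

    Positive values mean label i's edges close on themselves more than the
    label's edge-end share predicts; summing over labels gives the numerator
    of Newman's whole-graph coefficient.
    """
    labels = np.asarray(labels, dtype=str)
    pops = populations if populations is not None else sorted(set(labels))
    lut = {p: i for i, p in enumerate(pops)}
    codes = np.array([lut[l] for l in labels], dtype=np.intp)
    e = _mixing_matrix(graph, codes, len(pops))
    a, b = e.sum(axis=1), e.sum(axis=0)
    return pd.Series(np.diag(e) - a * b, index=pops, name="assortative_excess")


@dataclass
class TopologyResult:
    """Per-region topology summary: clustering (raw + corrected) and assortativity."""

    region_id: str
    clustering: pd.DataFrame          # output of corrected_clustering
    assortativity: float
    per_population: pd.Series         # e_ii − a_i b_i
    n_perm: int
    seed: int
    region_class: str | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.clustering.copy()
        out.insert(0, "region_id", self.region_id)
        out.insert(1, "region_class", self.region_class)
        out["assortativity_graph"] = self.assortativity
        out["assortative_excess"] = self.per_population.reindex(out["population"]).to_numpy()
        return out


def region_topology(graph: CellGraph, labels: np.ndarray,
                    populations: list[str] | None = None,
                    n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                    region_id: str = "", region_class: str | None = None) -> TopologyResult:
    """All topology descriptors for one region graph."""
    clustering = corrected_clustering(graph, labels, populations=populations,
                                      n_perm=n_perm, seed=seed, region_id=region_id)
    assort = label_assortativity(graph, labels, populations=populations)
    per_pop = per_population_assortativity(graph, labels, populations=populations)
    return TopologyResult(region_id=region_id, clustering=clustering,
                          assortativity=assort, per_population=per_pop,
                          n_perm=n_perm, seed=seed, region_class=region_class)
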