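"""Permutation-null spatial statistics on labeled cell point patterns.

The null model keeps every cell where it is and reshuffles the population
labels uniformly within the region (300 draws by default), so per-population
abundances are conserved exactly while any spatial structure in the labeling
is destroyed.  Each statistic is reported as observed − null mean
("difference from the value predicted by a random distribution of cells"),
with the null SD kept for diagnostics.  Group-level inference across regions
uses one-sample Wilcoxon signed-rank tests of the differences against zero
with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tissue import CellGraph, CellTable

__all__ = [
    "DEFAULT_N_PERM",
    "region_rng",
    "permute_labels",
    "EnrichmentResult",
    "distance_enrichment",
    "interaction_proportions",
    "interaction_enrichment",
    "group_test",
]

#: permutation draws per region
DEFAULT_N_PERM = 300


def region_rng(master_seed: int, region_id: str, statistic: str) -> np.random.Generator:
    """Independent, reproducible RNG stream per (region, statistic).

    Streams are derived from the master seed plus stable CRC32 hashes of the
    region id and statistic name, so each statistic's null is reproducible on
    its own regardless of evaluation order.
    """
    ss = np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF,
         zlib.crc32(str(region_id).encode()),
         zlib.crc32(statistic.encode())]
    )
    return np.random.default_rng(ss)


def permute_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the label vector (counts conserved)."""
    if len(labels) == 0:
        raise ValueError("cannot permute an empty region")
    return rng.permutation(labels)


@dataclass
class EnrichmentResult:
    """Observed / null-expected / difference matrices for one region."""

    region_id: str
    statistic_name: str
    populations: list[str]
    observed: np.ndarray         # (P, P); NaN where undefined
    expected: np.ndarray         # null mean, same shape
    null_sd: np.ndarray          # null SD, same shape
    diff: np.ndarray             # observed − expected
    n_perm: int
    seed: int
    region_class: str | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per population pair."""
        rows = []
        for i, pi in enumerate(self.populations):
            for j, pj in enumerate(self.populations):
                rows.append({
                    "region_id": self.region_id,
                    "region_class": self.region_class,
                    "statistic": self.statistic_name,
                    "pop_i": pi, "pop_j": pj,
                    "observed": self.observed[i, j],
                    "expected": self.expected[i, j],
                    "null_sd": self.null_sd[i, j],
                    "diff": self.diff[i, j],
                })
        return pd.DataFrame(rows)


def _codes(labels: np.ndarray, populations: list[str]) -> np.ndarray:
    lut = {p: i for i, p in enumerate(populations)}
    return np.array([lut[l] for l in labels], dtype=np.intp)


def canonical_order(cell_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(order, rank) sorting cells by id, so nulls are row-order invariant."""
    order = np.argsort(np.asarray(cell_ids, dtype=str), kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return order, rank


def _mean_nearest_matrix(dist: np.ndarray, codes: np.ndarray, n_pop: int) -> np.ndarray:
    """Mean nearest-distance matrix for one labeling.

    ``dist`` is the full pairwise distance matrix with +inf on the diagonal
    (self-pairs excluded).  Entry (i, j) is the mean, over population-i
    cells, of the distance to the nearest population-j cell; NaN where a
    population is absent or the only eligible target is the cell itself.
    """
    counts = np.bincount(codes, minlength=n_pop)
    out = np.full((n_pop, n_pop), np.nan)
    for j in range(n_pop):
        if counts[j] == 0:
            continue
        d_to_j = dist[:, codes == j].min(axis=1)   # inf only for a lone same-pop cell
        sums = np.bincount(codes, weights=np.where(np.isfinite(d_to_j), d_to_j, 0.0),
                           minlength=n_pop)
        fin = np.bincount(codes, weights=np.isfinite(d_to_j).astype(float),
                          minlength=n_pop)
        with np.errstate(invalid="ignore"):
            col = np.where(fin > 0, sums / np.maximum(fin, 1), np.nan)
        out[:, j] = col
    return out


def distance_enrichment(cells: CellTable, n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                        region_id: str | None = None) -> EnrichmentResult:
    """Nearest-distance enrichment: observed minus permutation-null mean.

    observed(i, j) = mean over population-i cells of the distance to the
    nearest population-j cell (self excluded); the null re-evaluates the same
    statistic under random relabelings of the region.  Negative diff(i, j)
    means populations i and j sit closer together than chance predicts.
    """
    region = cells.region(region_id) if region_id is not None else cells
    if len(region) < 2:
        raise ValueError("distance enrichment needs at least 2 cells")
    pops = region.populations
    if len(set(region.labels)) < 2:
        warnings.warn("fewer than 2 populations present; most entries undefined",
                      stacklevel=2)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    order, _ = canonical_order(region.df["cell_id"].to_numpy(str))
    xy = region.xy[order]
    dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    codes = _codes(region.labels[order], pops)
    n_pop = len(pops)
    observed = _mean_nearest_matrix(dist, codes, n_pop)
    rid = region.df["region_id"].iloc[0]
    rng = region_rng(seed, rid, "distance")
    draws = np.empty((n_perm, n_pop, n_pop))
    for t in range(n_perm):
        draws[t] = _mean_nearest_matrix(dist, permute_labels(codes, rng), n_pop)
    expected = np.nanmean(draws, axis=0)
    null_sd = np.nanstd(draws, axis=0, ddof=1) if n_perm > 1 else np.zeros_like(expected)
    return EnrichmentResult(
        region_id=rid, statistic_name="distance", populations=pops,
        observed=observed, expected=expected, null_sd=null_sd,
        diff=observed - expected, n_perm=n_perm, seed=seed,
        region_class=region.df["region_class"].iloc[0],
    )


def _proportion_matrix(edges: np.ndarray, codes: np.ndarray, n_pop: int) -> np.ndarray:
    """Edge-endpoint interaction proportions for one labeling.

    Entry (i, j): fraction of the edge endpoints of population-i cells that
    land on population-j cells.  Rows of populations with no edges are NaN.
    """
    counts = np.zeros((n_pop, n_pop))
    if len(edges):
        cu, cv = codes[edges[:, 0]], codes[edges[:, 1]]
        np.add.at(counts, (cu, cv), 1.0)
        np.add.at(counts, (cv, cu), 1.0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(row[:, None] > 0, counts / np.maximum(row[:, None], 1), np.nan)
    # populations absent from the graph entirely stay NaN
    present = np.bincount(codes, minlength=n_pop) > 0
    out[~present] = np.nan
    out[:, ~present] = np.nan
    return out


def interaction_proportions(graph: CellGraph, labels: np.ndarray,
                            populations: list[str] | None = None) -> pd.DataFrame:
    """Observed interaction-proportion matrix for a labeled graph.

    Entry (i, j) is the fraction of edge endpoints of population-i cells
    landing on population-j cells; rows sum to 1 for populations with at
    least one edge.  Rows of edge-isolated populations are NaN and flagged
    with a warning.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    labels = np.asarray(labels, dtype=str)
    pops = populations if populations is not None else sorted(set(labels))
    codes = _codes(labels, pops)
    observed = _proportion_matrix(graph.edges, codes, len(pops))
    iso = [pops[i] for i in range(len(pops))
           if np.isnan(observed[i]).all() and (codes == i).any()]
    if iso:
        warnings.warn(f"population(s) without edges: {iso}", stacklevel=2)
    return pd.DataFrame(observed, index=pops, columns=pops)


def interaction_enrichment(cells: CellTable, graph: CellGraph,
                           n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                           region_id: str | None = None) -> EnrichmentResult:
    """Interaction-proportion enrichment on a fixed graph.

    The graph topology is built once from cell positions and never
    recomputed; only labels shuffle under the null.  Positive diff(i, j)
    means i-cells interact with j-cells more than their abundances predict.
    """
    region = cells.region(region_id) if region_id is not None else cells
    if graph.n_nodes != len(region):
        raise ValueError("graph and region size mismatch")
    pops = region.populations
    order, rank = canonical_order(graph.nodes)
    codes = _codes(region.labels, pops)[order]
    edges = rank[graph.edges] if graph.n_edges else graph.edges
    n_pop = len(pops)
    observed = _proportion_matrix(edges, codes, n_pop)
    rid = region.df["region_id"].iloc[0]
    rng = region_rng(seed, rid, "interaction")
    draws = np.empty((n_perm, n_pop, n_pop))
    for t in range(n_perm):
        draws[t] = _proportion_matrix(edges, permute_labels(codes, rng), n_pop)
    expected = np.nanmean(draws, axis=0)
    null_sd = np.nanstd(draws, axis=0, ddof=1) if n_perm > 1 else np.zeros_like(expected)
    return EnrichmentResult(
        region_id=rid, statistic_name="interaction", populations=pops,
        observed=observed, expected=expected, null_sd=null_sd,
        diff=observed - expected, n_perm=n_perm, seed=seed,
        region_class=region.df["region_class"].iloc[0],
    )


def group_test(results: list[EnrichmentResult], grouping: str = "region_class",
               groups: list[str] | None = None) -> pd.DataFrame:
    """Cross-region Wilcoxon signed-rank tests of diff against 0, with BH.

    One value per region per population pair; regions are grouped (edge vs
    core by default) and the family of pair tests within each group is
    BH-adjusted.  Undefined entries are dropped pairwise; groups with < 2
    usable regions are skipped.
    """
    if not results:
        raise ValueError("no enrichment results supplied")
    pops = results[0].populations
    for r in results:
        if r.populations != pops:
            raise ValueError("results carry inconsistent population sets")
    if groups is None:
        if grouping == "region_class":
            groups = [r.region_class or "all" for r in results]
        else:
            groups = ["all"] * len(results)
    groups = np.asarray(groups, dtype=str)
    diffs = np.stack([r.diff for r in results])  # (R, P, P)
    rows = []
    for g in np.unique(groups):
        gm = groups == g
        grows = []
        for i, pi in enumerate(pops):
            for j, pj in enumerate(pops):
                vals = diffs[gm, i, j]
                vals = vals[np.isfinite(vals)]
                rec = {"group": g, "pop_i": pi, "pop_j": pj, "n_regions": len(vals),
                       "mean_diff": float(np.mean(vals)) if len(vals) else np.nan,
                       "p": np.nan, "degenerate": False, "tested": False}
                if len(vals) >= 2:
                    if np.allclose(vals, 0.0):
                        rec.update(p=1.0, degenerate=True, tested=True)
                    else:
                        stat_res = stats.wilcoxon(vals, alternative="two-sided")
                        rec.update(p=float(stat_res.pvalue), tested=True)
                grows.append(rec)
        tested = [r for r in grows if r["tested"]]
        if tested:
            padj = multipletests([r["p"] for r in tested], method="fdr_bh")[1]
            for r, pa in zip(tested, padj):
                r["p_adj"] = float(pa)
        for r in grows:
            r.setdefault("p_adj", np.nan)
        rows.extend(grows)
    return pd.DataFrame(rows)
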