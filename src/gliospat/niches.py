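"""Spot-level niche discovery and survival association.

Works on hex-grid spot datasets (Visium-style) carried as AnnData: raw gene
counts, per-spot population abundances from an upstream deconvolution, and
spot coordinates on an axial hexagonal grid.  The pipeline is: QC and
normalization, per-spot signature scoring (hypergeometric over-representation
of a gene set among each spot's top-expressed genes), abundance–factor
correlation screens, k-means clustering of standardized abundances into
myeloid environments, 6-neighbor spot-graph connectivity, extraction of
non-myeloid marker genes per environment, and univariate Cox association of
environment proportions with survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-exported for callers)
from statsmodels.stats.multitest import multipletests

from .environment import holm_sidak

__all__ = [
    "SpotDataset",
    "SurvivalCohort",
    "make_spot_dataset",
    "qc_normalize",
    "score_signature",
    "correlate_factors",
    "cluster_environments",
    "hex_neighbor_edges",
    "environment_connectivity",
    "nonmyeloid_signature",
    "environment_markers",
    "SurvivalResultRow",
    "survival_association",
]

UNASSIGNED = -1


@dataclass
class SpotDataset:
    """Hex-grid spot dataset wrapped around an AnnData.

    ``adata.X`` holds raw counts before :func:`qc_normalize` and
    log-normalized expression after (raw counts preserved in
    ``layers["counts"]``).  Hex axial coordinates live in
    ``obs["hex_col"]/obs["hex_row"]``, μm centers in ``obs["x_um"]/["y_um"]``,
    environment labels in ``obs["environment"]`` (−1 = unassigned), and the
    spots×populations abundance matrix in ``obsm["abundances"]``.
    """

    adata: ad.AnnData

    def __post_init__(self):
        ab = self.abundances.to_numpy(float)
        if not np.all(np.isfinite(ab)) or (ab < 0).any():
            raise ValueError("abundances must be finite and >= 0")

    @property
    def n_spots(self) -> int:
        return self.adata.n_obs

    @property
    def genes(self) -> list[str]:
        return list(self.adata.var_names)

    @property
    def abundances(self) -> pd.DataFrame:
        return self.adata.obsm["abundances"]

    @property
    def normalized(self) -> bool:
        return bool(self.adata.uns.get("normalized", False))

    @property
    def counts(self) -> np.ndarray:
        layer = self.adata.layers.get("counts")
        x = layer if layer is not None else self.adata.X
        return np.asarray(x, dtype=float)

    @property
    def expression(self) -> np.ndarray:
        if not self.normalized:
            raise ValueError("dataset not normalized yet; run qc_normalize")
        return np.asarray(self.adata.X, dtype=float)

    @property
    def environment(self) -> np.ndarray:
        if "environment" not in self.adata.obs:
            return np.full(self.n_spots, UNASSIGNED)
        return self.adata.obs["environment"].to_numpy(int)

    def set_environment(self, labels: np.ndarray) -> None:
        self.adata.obs["environment"] = np.asarray(labels, int)

    def hex_coords(self) -> np.ndarray:
        return self.adata.obs[["hex_col", "hex_row"]].to_numpy(int)

    def copy(self) -> "SpotDataset":
        return SpotDataset(self.adata.copy())


@dataclass
class SurvivalCohort:
    """Per-sample environment proportions plus right-censored survival."""

    df: pd.DataFrame                  # sample_id, time, event, one column per env
    env_cols: list[str] = field(default_factory=list)

    def __post_init__(self):
        for col in ("sample_id", "time", "event"):
            if col not in self.df.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        if not self.env_cols:
            self.env_cols = [c for c in self.df.columns
                             if c not in ("sample_id", "time", "event")]
        t = self.df["time"].to_numpy(float)
        if np.isnan(t).any() or (t <= 0).any():
            raise ValueError("survival times must be positive and non-missing")
        ev = set(self.df["event"].unique())
        if not ev <= {0, 1}:
            raise ValueError("event flags must be 0/1")
        props = self.df[self.env_cols].to_numpy(float)
        if not np.all(np.isfinite(props)) or (props < 0).any():
            raise ValueError("environment proportions must be finite and >= 0")


def make_spot_dataset(counts: pd.DataFrame, coords: pd.DataFrame,
                      abundances: pd.DataFrame, batch: pd.Series | None = None) -> SpotDataset:
    """Assemble a SpotDataset from spots×genes counts, hex coords and abundances.

    ``coords`` needs columns hex_col, hex_row and optionally x_um, y_um.  A
    ``batch`` column is accepted for interface compatibility but ignored
    (single-batch analysis), with a warning.
    """
    if batch is not None:
        warnings.warn("batch labels accepted but ignored (single-batch analysis)",
                      stacklevel=2)
    if not counts.index.equals(coords.index) or not counts.index.equals(abundances.index):
        raise ValueError("counts, coords and abundances must share the spot index")
    x = counts.to_numpy(float)
    if (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be non-negative integers")
    adata = ad.AnnData(
        X=x, obs=pd.DataFrame(index=counts.index.astype(str)),
        var=pd.DataFrame(index=counts.columns.astype(str)),
    )
    adata.obs["hex_col"] = coords["hex_col"].to_numpy(int)
    adata.obs["hex_row"] = coords["hex_row"].to_numpy(int)
    for c in ("x_um", "y_um"):
        if c in coords.columns:
            adata.obs[c] = coords[c].to_numpy(float)
    adata.obsm["abundances"] = abundances.astype(float).set_axis(adata.obs_names)
    adata.uns["normalized"] = False
    return SpotDataset(adata)


def qc_normalize(spots: SpotDataset, min_counts: int = 1000,
                 mito_prefixes: tuple[str, ...] = ("MT-",)) -> SpotDataset:
    """Drop low-count spots and mitochondrial genes, normalize, log-transform.

    Spots with total counts strictly below ``min_counts`` are removed, genes
    whose names start with a mitochondrial prefix are removed, and the
    remaining counts are library-size scaled per spot to the median
    pre-scaling total, then log(1 + x) transformed.
    """
    import scanpy as sc

    if spots.normalized:
        raise ValueError("dataset is already normalized")
    adata = spots.adata.copy()
    keep_genes = ~adata.var_names.str.startswith(tuple(mito_prefixes))
    adata = adata[:, keep_genes].copy()
    totals = np.asarray(adata.X).sum(axis=1)
    keep_spots = totals >= min_counts
    if not keep_spots.any():
        raise ValueError("all spots fail the QC count threshold")
    adata = adata[keep_spots].copy()
    adata.obsm["abundances"] = spots.abundances.loc[adata.obs_names]
    adata.layers["counts"] = np.asarray(adata.X).copy()
    sc.pp.normalize_total(adata, target_sum=None)   # median spot total
    sc.pp.log1p(adata)
    adata.uns["normalized"] = True
    adata.uns["qc"] = {"n_spots_removed": int((~keep_spots).sum()),
                       "n_genes_removed": int((~keep_genes).sum()),
                       "min_counts": int(min_counts)}
    return SpotDataset(adata)


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------

def score_signature(spots: SpotDataset, gene_set: list[str],
                    top_fraction: float = 0.05) -> np.ndarray:
    """Per-spot −log10 hypergeometric over-representation score of a gene set.

    For each spot the ``top_fraction`` highest-expressed genes (ties broken
    by gene name) form the selected set; the score is −log10 of the
    upper-tail hypergeometric probability of the observed overlap with the
    gene set, with universe = all retained genes.
    """
    genes = np.array(spots.genes)
    in_set = np.isin(genes, list(gene_set))
    big_k = int(in_set.sum())
    if big_k == 0:
        raise ValueError("gene set has no overlap with the dataset's genes")
    expr = spots.expression
    n_genes = len(genes)
    n_sel = max(1, int(np.ceil(top_fraction * n_genes)))
    # deterministic selection: sort by (-expression, gene name)
    name_rank = np.argsort(np.argsort(genes))
    scores = np.empty(spots.n_spots)
    for s in range(spots.n_spots):
        order = np.lexsort((name_rank, -expr[s]))
        sel = order[:n_sel]
        k = int(in_set[sel].sum())
        p = stats.hypergeom.sf(k - 1, n_genes, big_k, n_sel)
        scores[s] = -np.log10(max(p, np.finfo(float).tiny))
    return scores


def correlate_factors(abundances: pd.DataFrame, factors: pd.DataFrame,
                      min_factor_sd: float = 0.05) -> pd.DataFrame:
    """Pearson screen of per-spot factors against population abundances.

    Factors with SD below ``min_factor_sd`` are dropped before testing
    (reported with ``excluded=True`` rows); all remaining factor×population
    correlations are BH-adjusted together.
    """
    rows = []
    sds = factors.std(ddof=0)
    kept = [f for f in factors.columns if sds[f] >= min_factor_sd]
    dropped = [f for f in factors.columns if f not in kept]
    for f in dropped:
        rows.append({"factor": f, "population": None, "r": np.nan, "p": np.nan,
                     "excluded": True, "flag": "factor SD below threshold"})
    tested = []
    for f in kept:
        for pop in abundances.columns:
            a = abundances[pop].to_numpy(float)
            if np.std(a) == 0:
                rows.append({"factor": f, "population": pop, "r": np.nan,
                             "p": np.nan, "excluded": False,
                             "flag": "constant abundance"})
                continue
            r, p = stats.pearsonr(factors[f].to_numpy(float), a)
            rec = {"factor": f, "population": pop, "r": float(r), "p": float(p),
                   "excluded": False, "flag": ""}
            rows.append(rec)
            tested.append(rec)
    if tested:
        padj = multipletests([t["p"] for t in tested], method="fdr_bh")[1]
        for t, pa in zip(tested, padj):
            t["p_adj"] = float(pa)
    out = pd.DataFrame(rows)
    if "p_adj" not in out.columns:
        out["p_adj"] = np.nan
    return out


# ---------------------------------------------------------------------------
# environment discovery
# ---------------------------------------------------------------------------

def cluster_environments(abundances: pd.DataFrame, k: int = 5, seed: int = 0,
                         n_init: int = 10) -> np.ndarray:
    """K-means clustering of standardized abundances into myeloid environments.

    Columns are scaled to zero mean / unit variance across spots; labels are
    renumbered in descending cluster size (ties by original label) so the
    labeling is deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = abundances.to_numpy(float)
    if k > len(x):
        raise ValueError("k exceeds the number of spots")
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) & 0x7FFFFFFF)
    raw = km.fit_predict(z)
    sizes = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))     # descending size, stable
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]


#: axial hex-grid neighbor offsets (pointy-top axial coordinates)
HEX_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


def hex_neighbor_edges(hex_coords: np.ndarray) -> np.ndarray:
    """Undirected edges between axially adjacent spots (≤ 6 neighbors each)."""
    index = {(int(c), int(r)): i for i, (c, r) in enumerate(hex_coords)}
    edges = set()
    for i, (c, r) in enumerate(hex_coords):
        for dc, dr in HEX_OFFSETS:
            j = index.get((int(c) + dc, int(r) + dr))
            if j is not None and j != i:
                edges.add((min(i, j), max(i, j)))
    if not edges:
        return np.empty((0, 2), dtype=int)
    return np.array(sorted(edges), dtype=int)


def environment_connectivity(spots: SpotDataset) -> pd.DataFrame:
    """Environment×environment spot-adjacency proportions on the hex grid.

    Entry (e, f) is the fraction of environment-e spot-edge endpoints whose
    neighbor is in environment f; rows sum to 1 for environments with at
    least one adjacency.  Unassigned spots are excluded (count warned).
    """
    env = spots.environment
    unassigned = env == UNASSIGNED
    if unassigned.any():
        warnings.warn(f"{int(unassigned.sum())} unassigned spot(s) excluded "
                      "from connectivity", stacklevel=2)
    edges = hex_neighbor_edges(spots.hex_coords())
    keep = ~(unassigned[edges[:, 0]] | unassigned[edges[:, 1]]) if len(edges) else []
    edges = edges[keep] if len(edges) else edges
    envs = np.unique(env[~unassigned])
    lut = {e: i for i, e in enumerate(envs)}
    counts = np.zeros((len(envs), len(envs)))
    for u, v in edges:
        eu, ev = lut[env[u]], lut[env[v]]
        counts[eu, ev] += 1
        counts[ev, eu] += 1
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        props = np.where(row[:, None] > 0, counts / np.maximum(row[:, None], 1), np.nan)
    return pd.DataFrame(props, index=envs, columns=envs)


def nonmyeloid_signature(signatures: pd.DataFrame, sd_threshold: float = 0.1) -> tuple[list[str], int]:
    """Genes whose reference expression barely varies across myeloid populations.

    ``signatures`` is populations×genes on the counts scale.  Genes with
    SD > ``sd_threshold`` across populations are excluded (they carry
    myeloid identity); the retained list captures non-myeloid signal.
    Returns (retained gene list, number excluded).
    """
    if signatures.size == 0:
        raise ValueError("empty signature matrix")
    sds = signatures.std(axis=0, ddof=0)
    retained = [g for g in signatures.columns if sds[g] <= sd_threshold]
    return retained, int(len(signatures.columns) - len(retained))


def environment_markers(spots: SpotDataset, gene_subset: list[str],
                        p_max: float = 0.01, min_fold: float = 1.5) -> dict[int, pd.DataFrame]:
    """One-vs-rest Wilcoxon rank-sum marker genes per environment.

    Tested on normalized expression restricted to ``gene_subset``; kept
    genes satisfy raw p < ``p_max`` and fold ≥ ``min_fold``, the fold being
    the ratio of expm1-backtransformed group means (pseudocount 1e−9).
    Environments with < 3 spots are skipped (warned).
    """
    genes = [g for g in spots.genes if g in set(gene_subset)]
    if not genes:
        raise ValueError("gene subset has no overlap with the dataset's genes")
    gi = [spots.genes.index(g) for g in genes]
    expr = spots.expression[:, gi]
    env = spots.environment
    out: dict[int, pd.DataFrame] = {}
    eps = 1e-9
    for e in np.unique(env[env != UNASSIGNED]):
        mask = env == e
        if mask.sum() < 3 or (~mask & (env != UNASSIGNED)).sum() < 3:
            warnings.warn(f"environment {e} has too few spots; skipped", stacklevel=2)
            continue
        rest = ~mask & (env != UNASSIGNED)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals = stats.mannwhitneyu(expr[mask], expr[rest], axis=0,
                                       alternative="two-sided").pvalue
        mean_in = np.expm1(expr[mask]).mean(axis=0)
        mean_out = np.expm1(expr[rest]).mean(axis=0)
        fold = (mean_in + eps) / (mean_out + eps)
        keep = (pvals < p_max) & (fold >= min_fold)
        df = pd.DataFrame({"gene": np.array(genes)[keep], "p": pvals[keep],
                           "fold": fold[keep]}).sort_values("p", kind="stable")
        out[int(e)] = df.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResultRow:
    environment: str
    log_hr: float                 # per percentage point
    hr: float
    se: float
    p: float
    p_adj: float
    defined: bool = True
    flag: str = ""


def survival_association(cohort: SurvivalCohort, split: str = "median",
                         scale_percent: bool = True):
    """Univariate Cox association of each environment proportion with survival.

    One proportional-hazards fit per environment (partial likelihood via
    lifelines), hazard ratios per percentage point of environment abundance,
    Holm-Šídák adjusted across environments.  Also returns the median (or
    mean) split used for Kaplan-Meier comparison, with log-rank p per
    environment.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    df = cohort.df
    if len(df) < 20:
        raise ValueError("cohort too small (< 20 samples)")
    if int(df["event"].sum()) < 5:
        raise ValueError("too few events (< 5)")
    rows: list[SurvivalResultRow] = []
    km = {}
    for env in cohort.env_cols:
        x = df[env].to_numpy(float)
        cov = x * 100.0 if scale_percent else x
        if np.std(cov) == 0:
            rows.append(SurvivalResultRow(env, np.nan, np.nan, np.nan, np.nan,
                                          np.nan, defined=False,
                                          flag="constant covariate"))
            continue
        fit_df = pd.DataFrame({"time": df["time"], "event": df["event"], env: cov})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(fit_df, duration_col="time", event_col="event")
            beta = float(cph.params_[env])
            se = float(cph.standard_errors_[env])
            p = float(cph.summary.loc[env, "p"])
            rows.append(SurvivalResultRow(env, beta, float(np.exp(beta)), se, p, np.nan))
        except Exception as err:  # pragma: no cover - degenerate fits
            rows.append(SurvivalResultRow(env, np.nan, np.nan, np.nan, np.nan,
                                          np.nan, defined=False,
                                          flag=f"non-convergence: {err}"))
            continue
        cut = np.median(x) if split == "median" else np.mean(x)
        high = x > cut
        if 0 < high.sum() < len(x):
            lr = logrank_test(df.loc[high, "time"], df.loc[~high, "time"],
                              df.loc[high, "event"], df.loc[~high, "event"])
            km[env] = {"high_mask": high, "cut": float(cut),
                       "logrank_p": float(lr.p_value)}
    defined = [r for r in rows if r.defined]
    if defined:
        padj = holm_sidak([r.p for r in defined])
        for r, pa in zip(defined, padj):
            r.p_adj = float(pa)
    table = pd.DataFrame([r.__dict__ for r in rows])
    return table, km
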