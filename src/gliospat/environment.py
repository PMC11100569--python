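"""Per-cell microenvironment quantification.

Four views of a cell's surroundings: phenotypic diversity of its direct
contacts (Rao's quadratic entropy), mean marker intensity in a 40-μm window
of the raster around it, co-occurrence of two populations within a fixed
radius against a label-permutation null (cross-PCF), and distance-based
vascular association classes.  Group comparisons of these per-cell values
respect the sampling hierarchy (cells within regions within cases) through
a linear mixed model with nested random intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .permutation import DEFAULT_N_PERM, permute_labels, region_rng
from .tissue import CellGraph, CellTable, MarkerRaster

__all__ = [
    "rao_entropy",
    "rao_entropy_all",
    "window_expression",
    "CrossPCFResult",
    "cross_pcf",
    "vascular_classes",
    "infiltration_rate",
    "NestedCompareResult",
    "nested_compare",
    "holm_sidak",
]

VASCULAR_CLASSES = ("vascular", "perivascular", "infiltrated")


# ---------------------------------------------------------------------------
# Rao's quadratic entropy
# ---------------------------------------------------------------------------

def _rao_q(pheno: np.ndarray) -> float:
    """Q = Σᵢ Σⱼ pᵢ pⱼ d(i, j), uniform weights, Euclidean phenotype distance."""
    m = len(pheno)
    d = np.sqrt(((pheno[:, None, :] - pheno[None, :, :]) ** 2).sum(-1))
    return float(d.sum()) / (m * m)


def rao_entropy(cell_index: int, graph: CellGraph, phenotypes: np.ndarray) -> float:
    """Rao's quadratic entropy of one cell's contact neighborhood.

    The neighborhood is the cell plus its direct contact neighbors, weighted
    uniformly; the phenotype distance is Euclidean over normalized marker
    vectors.  Isolated cells return 0 (flagged).
    """
    if not (0 <= cell_index < graph.n_nodes):
        raise KeyError(f"unknown cell index {cell_index}")
    adj = graph.adjacency()
    nbrs = adj.indices[adj.indptr[cell_index]:adj.indptr[cell_index + 1]]
    if len(nbrs) == 0:
        warnings.warn(f"cell {cell_index} has no contacts; entropy 0", stacklevel=2)
        return 0.0
    hood = np.r_[cell_index, nbrs]
    return _rao_q(np.asarray(phenotypes, float)[hood])


def rao_entropy_all(graph: CellGraph, phenotypes: np.ndarray) -> np.ndarray:
    """Vectorized :func:`rao_entropy` over every cell of the graph."""
    pheno = np.asarray(phenotypes, float)
    adj = graph.adjacency()
    out = np.zeros(graph.n_nodes)
    for c in range(graph.n_nodes):
        nbrs = adj.indices[adj.indptr[c]:adj.indptr[c + 1]]
        if len(nbrs):
            out[c] = _rao_q(pheno[np.r_[c, nbrs]])
    return out


# ---------------------------------------------------------------------------
# window expression
# ---------------------------------------------------------------------------

def window_expression(cells: CellTable, raster: MarkerRaster, window_um: float = 40.0,
                      shape: str = "square") -> np.ndarray:
    """Mean raster intensity in a window centered on each cell.

    ``square`` (default): axis-aligned square of side ``window_um``;
    ``disc``: disc of diameter ``window_um``.  A pixel belongs to the window
    when its center falls inside; windows are clipped at raster borders and
    the mean is taken over in-bounds pixels only.  Cells whose window holds
    no pixel centers get NaN (flagged).
    """
    if not (window_um > 0):
        raise ValueError("window_um must be > 0")
    if shape not in ("square", "disc"):
        raise ValueError(f"unknown window shape {shape!r}")
    grid, s = raster.grid, raster.scale
    ox, oy = raster.origin
    h, w = grid.shape
    half = window_um / 2.0
    out = np.full(len(cells), np.nan)
    n_empty = 0
    for c, (cx, cy) in enumerate(cells.xy):
        j_lo = max(0, int(np.ceil((cx - half - ox) / s - 0.5)))
        j_hi = min(w - 1, int(np.floor((cx + half - ox) / s - 0.5)))
        i_lo = max(0, int(np.ceil((cy - half - oy) / s - 0.5)))
        i_hi = min(h - 1, int(np.floor((cy + half - oy) / s - 0.5)))
        if j_hi < j_lo or i_hi < i_lo:
            n_empty += 1
            continue
        block = grid[i_lo:i_hi + 1, j_lo:j_hi + 1]
        if shape == "disc":
            jj = ox + (np.arange(j_lo, j_hi + 1) + 0.5) * s
            ii = oy + (np.arange(i_lo, i_hi + 1) + 0.5) * s
            mask = ((ii[:, None] - cy) ** 2 + (jj[None, :] - cx) ** 2) <= half ** 2
            if not mask.any():
                n_empty += 1
                continue
            out[c] = float(block[mask].mean())
        else:
            out[c] = float(block.mean())
    if n_empty:
        warnings.warn(f"{n_empty} cell window(s) contained no pixel centers; NaN",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# cross-PCF
# ---------------------------------------------------------------------------

@dataclass
class CrossPCFResult:
    """Pairwise co-occurrence statistic vs its label-permutation null."""

    pop_a: str
    pop_b: str
    radius_um: float
    observed: float
    expected: float
    null_sd: float
    diff: float
    p_value: float
    n_perm: int
    defined: bool = True


def cross_pcf(cells: CellTable, pop_a: str, pop_b: str, radius_um: float = 20.0,
              n_perm: int = DEFAULT_N_PERM, seed: int = 0,
              region_id: str | None = None) -> CrossPCFResult:
    """Co-occurrence of two populations within ``radius_um`` vs chance.

    observed = #{(a, b) cell pairs with centroid distance ≤ radius} / (nₐ·n_b),
    compared against the same count under random relabelings of the region.
    The empirical two-sided p carries the add-one correction, so it can never
    be exactly zero.
    """
    from .permutation import canonical_order

    region = cells.region(region_id) if region_id is not None else cells
    order, _ = canonical_order(region.df["cell_id"].to_numpy(str))
    labels = region.labels[order]
    n_a, n_b = int((labels == pop_a).sum()), int((labels == pop_b).sum())
    if n_a == 0 or n_b == 0:
        warnings.warn(f"empty population in pair ({pop_a!r}, {pop_b!r}); "
                      "cross-PCF undefined", stacklevel=2)
        return CrossPCFResult(pop_a, pop_b, radius_um, np.nan, np.nan, np.nan,
                              np.nan, np.nan, n_perm, defined=False)
    tree = cKDTree(region.xy[order])
    pairs = tree.query_pairs(radius_um, output_type="ndarray")  # positions fixed

    def count(lab: np.ndarray) -> float:
        if len(pairs) == 0:
            return 0.0
        lu, lv = lab[pairs[:, 0]], lab[pairs[:, 1]]
        if pop_a == pop_b:
            c = np.count_nonzero((lu == pop_a) & (lv == pop_a))
        else:
            c = np.count_nonzero(((lu == pop_a) & (lv == pop_b)) |
                                 ((lu == pop_b) & (lv == pop_a)))
        return c / (n_a * n_b)

    observed = count(labels)
    rid = region.df["region_id"].iloc[0]
    rng = region_rng(seed, rid, "cross_pcf")
    null = np.array([count(permute_labels(labels, rng)) for _ in range(n_perm)])
    expected = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    p_ge = (1 + np.count_nonzero(null >= observed)) / (n_perm + 1)
    p_le = (1 + np.count_nonzero(null <= observed)) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_ge, p_le))
    return CrossPCFResult(pop_a, pop_b, radius_um, float(observed), expected,
                          null_sd, float(observed) - expected, float(p), n_perm)


# ---------------------------------------------------------------------------
# vascular association
# ---------------------------------------------------------------------------

def vascular_classes(cells: CellTable, vascular_pop: str, near_um: float = 0.0,
                     far_um: float = 10.0, region_id: str | None = None) -> pd.DataFrame:
    """Distance to the nearest vascular cell and the resulting class.

    Classes: ``vascular`` at distance ≤ near_um (direct association),
    ``perivascular`` in (near_um, far_um], ``infiltrated`` beyond far_um.
    Vascular cells themselves have distance 0.  Regions without vascular
    cells get NaN distances and no classes (warned).
    """
    if not (0 <= near_um < far_um):
        raise ValueError("need 0 <= near_um < far_um")
    region = cells.region(region_id) if region_id is not None else cells
    labels = region.labels
    vmask = labels == vascular_pop
    out = pd.DataFrame({
        "cell_id": region.df["cell_id"].to_numpy(),
        "population": labels,
        "distance_to_vessel": np.nan,
        "vascular_class": pd.Categorical([None] * len(region),
                                         categories=list(VASCULAR_CLASSES)),
    })
    if not vmask.any():
        warnings.warn("region has no vascular cells; classification skipped",
                      stacklevel=2)
        return out
    tree = cKDTree(region.xy[vmask])
    d, _ = tree.query(region.xy, k=1)
    d = np.asarray(d, float)
    d[vmask] = 0.0
    cls = np.where(d <= near_um, "vascular",
                   np.where(d <= far_um, "perivascular", "infiltrated"))
    out["distance_to_vessel"] = d
    out["vascular_class"] = pd.Categorical(cls, categories=list(VASCULAR_CLASSES))
    return out


def infiltration_rate(classified: pd.DataFrame, population: str | None = None) -> float:
    """Fraction of classified cells in class ``infiltrated`` (optionally one population)."""
    df = classified.dropna(subset=["vascular_class"])
    if population is not None:
        df = df[df["population"] == population]
    if len(df) == 0:
        return np.nan
    return float((df["vascular_class"] == "infiltrated").mean())


# ---------------------------------------------------------------------------
# nested mixed-model comparison
# ---------------------------------------------------------------------------

def holm_sidak(pvals) -> np.ndarray:
    """Holm-Šídák step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, float), method="holm-sidak")[1]


@dataclass
class NestedCompareResult:
    """Factor contrasts from a nested linear mixed model."""

    contrasts: pd.DataFrame       # contrast, estimate, se, p, p_adj
    method: str                   # "lmm" | "lmm_case_only" | "wilcoxon_fallback"
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def p_adj(self) -> np.ndarray:
        return self.contrasts["p_adj"].to_numpy()

    def summary(self) -> pd.DataFrame:
        return self.contrasts


def nested_compare(df: pd.DataFrame, value: str = "value", factor: str = "population",
                   case: str = "case_id", region: str = "region_id") -> NestedCompareResult:
    """Compare a per-cell value between factor levels, respecting nesting.

    Fits a linear mixed model of the value on the factor with random
    intercepts for case and for region nested within case (REML).  The
    family of factor-level contrasts (each level vs the reference) is
    Holm-Šídák adjusted.  With a single region per case the region term is
    dropped (flagged); on non-convergence the comparison falls back to
    Mann-Whitney tests on region means (flagged).
    """
    import statsmodels.formula.api as smf

    data = df[[value, factor, case, region]].dropna().copy()
    data.columns = ["value", "factor", "case", "region"]
    levels = sorted(data["factor"].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 factor levels to compare")
    if data["case"].nunique() < 2:
        raise ValueError("need >= 2 cases for the nested model")
    data["factor"] = pd.Categorical(data["factor"].astype(str), categories=levels)
    data["region_key"] = data["case"].astype(str) + ":" + data["region"].astype(str)
    flags: list[str] = []
    one_region = (data.groupby("case")["region_key"].nunique() <= 1).all()
    method = "lmm"
    if one_region:
        flags.append("single region per case; case-only random intercept")
        method = "lmm_case_only"

    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if one_region:
                model = smf.mixedlm("value ~ C(factor)", data=data, groups=data["case"])
            else:
                model = smf.mixedlm("value ~ C(factor)", data=data, groups=data["case"],
                                    re_formula="1",
                                    vc_formula={"region": "0 + C(region_key)"})
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        converged = bool(res.converged) and np.isfinite(res.bse.iloc[:len(levels)]).all()
    except Exception:
        converged = False
    if res is None or not converged:
        # region-mean Mann-Whitney fallback, one test per non-reference level
        flags.append("mixed model did not converge; region-mean rank fallback")
        means = (data.groupby(["region_key", "factor"], observed=True)["value"]
                 .mean().reset_index())
        ref = levels[0]
        rows = []
        for lev in levels[1:]:
            a = means.loc[means["factor"] == ref, "value"].to_numpy()
            b = means.loc[means["factor"] == lev, "value"].to_numpy()
            est = float(np.mean(b) - np.mean(a))
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            rows.append({"contrast": f"{lev} - {ref}", "estimate": est,
                         "se": np.nan, "p": p})
        contrasts = pd.DataFrame(rows)
        contrasts["p_adj"] = holm_sidak(contrasts["p"])
        return NestedCompareResult(contrasts, "wilcoxon_fallback", False, flags)

    rows = []
    for lev in levels[1:]:
        name = f"C(factor)[T.{lev}]"
        rows.append({"contrast": f"{lev} - {levels[0]}",
                     "estimate": float(res.params[name]),
                     "se": float(res.bse[name]),
                     "p": float(res.pvalues[name])})
    contrasts = pd.DataFrame(rows)
    contrasts["p_adj"] = holm_sidak(contrasts["p"])
    return NestedCompareResult(contrasts, method, True, flags)
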