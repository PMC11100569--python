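"""Data model, I/O, marker normalization and spatial graphs for segmented-cell tables.

The central container is :class:`CellTable`, a thin wrapper around a pandas
DataFrame holding one row per segmented cell: centroid coordinates in μm,
case/region identifiers, a region class (tumor ``edge`` or ``core``), a
population label, and per-marker mean intensities.  Marker rasters
(:class:`MarkerRaster`) are single-channel intensity grids aligned to the
same μm coordinate frame, and :class:`CellGraph` is the undirected spatial
neighborhood graph (six-nearest-neighbor or centroid-contact) on which all
interaction statistics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "SchemaError",
    "IntegrityError",
    "CellTable",
    "MarkerRaster",
    "CellGraph",
    "read_cell_table",
    "normalize_markers",
    "build_graph",
    "nearest_distances",
]

#: canonical column names of a cell table
REQUIRED_COLUMNS = ("cell_id", "x", "y", "case_id", "region_id", "region_class", "population")

REGION_CLASSES = ("edge", "core")


class SchemaError(ValueError):
    """A required column is missing or mis-typed in an input table."""


class IntegrityError(ValueError):
    """An input table violates a structural invariant (e.g. duplicate ids)."""


class CellTable:
    """Segmented single-cell table: one row per cell, μm coordinates.

    Parameters
    ----------
    df :
        DataFrame containing the canonical columns ``cell_id, x, y, case_id,
        region_id, region_class, population`` plus one numeric column per
        marker.  Extra columns are carried along untouched.
    marker_cols :
        Names of the marker-intensity columns.
    populations :
        Declared finite label set.  Defaults to the labels present.
    """

    def __init__(self, df: pd.DataFrame, marker_cols: list[str] | None = None,
                 populations: list[str] | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise IntegrityError(f"duplicate cell_id: {dup!r}")
        xy = df[["x", "y"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise IntegrityError("non-finite cell coordinates")
        bad_class = set(df["region_class"].unique()) - set(REGION_CLASSES)
        if bad_class:
            raise SchemaError(f"unknown region_class value(s): {sorted(bad_class)}")
        self.df = df.reset_index(drop=True)
        if marker_cols is None:
            marker_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS
                           and pd.api.types.is_numeric_dtype(df[c])]
        for c in marker_cols:
            if not pd.api.types.is_numeric_dtype(df[c]):
                raise SchemaError(f"marker column {c!r} is not numeric")
        self.marker_cols = list(marker_cols)
        if populations is None:
            populations = sorted(df["population"].astype(str).unique())
        self.populations = list(populations)
        unknown = set(df["population"].astype(str)) - set(self.populations)
        if unknown:
            raise IntegrityError(f"population label(s) outside declared set: {sorted(unknown)}")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(float)

    @property
    def labels(self) -> np.ndarray:
        return self.df["population"].astype(str).to_numpy()

    def markers(self) -> pd.DataFrame:
        return self.df[self.marker_cols]

    def region_keys(self) -> list[tuple[str, str]]:
        """(case_id, region_id) pairs, in first-appearance order."""
        seen = self.df[["case_id", "region_id"]].drop_duplicates()
        return list(seen.itertuples(index=False, name=None))

    def region(self, region_id: str, case_id: str | None = None) -> "CellTable":
        """View of one region as a new CellTable (copy)."""
        mask = self.df["region_id"] == region_id
        if case_id is not None:
            mask &= self.df["case_id"] == case_id
        if not mask.any():
            raise KeyError(f"region {region_id!r} not present")
        return CellTable(self.df.loc[mask].reset_index(drop=True),
                         marker_cols=self.marker_cols, populations=self.populations)

    def iter_regions(self):
        for case_id, region_id in self.region_keys():
            yield (case_id, region_id), self.region(region_id, case_id)

    def write_csv(self, path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)


@dataclass
class MarkerRaster:
    """Single-channel 2-D intensity grid on the cell coordinate frame.

    Pixel-center convention: pixel (i, j) has its center at
    ``origin + ((j + 0.5) * scale, (i + 0.5) * scale)`` in (x, y) μm, i.e.
    rows index y and columns index x.
    """

    channel: str
    grid: np.ndarray
    scale: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("raster grid must be 2-D")
        if not (self.scale > 0):
            raise ValueError("raster scale must be > 0")
        if not np.all(np.isfinite(self.grid)) or (self.grid < 0).any():
            raise ValueError("raster values must be finite and >= 0")

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the raster in μm."""
        h, w = self.grid.shape
        return w * self.scale, h * self.scale

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        w, h = self.extent_um
        ox, oy = self.origin
        return (x >= ox) & (x <= ox + w) & (y >= oy) & (y <= oy + h)

    def write_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.grid.astype(np.float32))

    @classmethod
    def read_tiff(cls, path, channel: str, scale: float = 1.0,
                  origin: tuple[float, float] = (0.0, 0.0)) -> "MarkerRaster":
        import tifffile

        return cls(channel=channel, grid=tifffile.imread(path), scale=scale, origin=origin)


@dataclass
class CellGraph:
    """Undirected spatial neighborhood graph on one region's cells.

    ``edges`` holds index pairs (u < v) into ``nodes``; the k-NN relation is
    symmetrized by edge union, so every node keeps at least its own k
    neighbors.
    """

    nodes: np.ndarray                     # cell_id per node
    edges: np.ndarray                     # (m, 2) int, u < v
    mode: str                             # "knn" | "contact"
    k: int | None = None
    contact_radius: float | None = None
    _adj: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sparse.csr_matrix:
        """Boolean CSR adjacency matrix (symmetric, zero diagonal)."""
        if self._adj is None:
            n = self.n_nodes
            if self.n_edges:
                u, v = self.edges[:, 0], self.edges[:, 1]
                data = np.ones(2 * len(u), dtype=np.int8)
                a = sparse.coo_matrix(
                    (data, (np.r_[u, v], np.r_[v, u])), shape=(n, n))
                self._adj = a.tocsr()
            else:
                self._adj = sparse.csr_matrix((n, n), dtype=np.int8)
        return self._adj

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def to_networkx(self, labels: np.ndarray | None = None):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        if labels is not None:
            nx.set_node_attributes(g, dict(enumerate(labels)), "population")
        return g


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_cell_table(path, schema: dict | None = None, marker_cols: list[str] | None = None,
                    sep: str | None = None) -> CellTable:
    """Read a CSV/TSV cell table, mapping file columns onto the canonical schema.

    ``schema`` maps canonical names (``cell_id``, ``x``, ...) to the column
    names used in the file; omitted keys default to the canonical name
    itself.  All unmapped numeric columns are treated as markers unless
    ``marker_cols`` restricts them.
    """
    schema = dict(schema or {})
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    rename = {}
    for canon in REQUIRED_COLUMNS:
        src = schema.get(canon, canon)
        if src not in df.columns:
            raise SchemaError(f"missing mapped column for {canon!r}: {src!r}")
        rename[src] = canon
    df = df.rename(columns=rename)
    if marker_cols is None:
        # candidate markers: every unmapped column with any numeric content;
        # fully non-numeric columns ride along as metadata
        marker_cols = []
        for c in df.columns:
            if c in REQUIRED_COLUMNS:
                continue
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.notna().all():
                marker_cols.append(c)
            elif coerced.notna().any():
                row = int(np.flatnonzero((coerced.isna() & df[c].notna()).to_numpy())[0])
                raise SchemaError(
                    f"non-numeric marker value in column {c!r} at row {row}")
    for c in marker_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SchemaError(f"non-numeric marker value in column {c!r} at row {row}")
        df[c] = vals
    df["cell_id"] = df["cell_id"].astype(str)
    return CellTable(df, marker_cols=marker_cols)


def normalize_markers(cells: CellTable, percentile: float = 99.0) -> CellTable:
    """Scale each marker to its own upper percentile, clipping into [0, 1].

    Each marker column is divided by its ``percentile``-th percentile taken
    over all cells, then clipped at 1; a marker whose percentile value is 0
    maps to all-zeros.
    """
    if len(cells) == 0:
        raise ValueError("cannot normalize an empty cell table")
    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    df = cells.df.copy()
    vals = df[cells.marker_cols].to_numpy(float)
    if (vals < 0).any():
        raise ValueError("negative marker intensity encountered")
    denom = np.percentile(vals, percentile, axis=0)
    out = np.zeros_like(vals)
    nz = denom > 0
    out[:, nz] = np.clip(vals[:, nz] / denom[nz], 0.0, 1.0)
    df[cells.marker_cols] = out
    return CellTable(df, marker_cols=cells.marker_cols, populations=cells.populations)


def _knn_edges(xy: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Symmetrized k-NN edge list; distance ties broken by cell_id order."""
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1) if n <= 2000 else None
    # lexicographic rank of cell ids, used only for tie-breaking
    id_rank = np.argsort(np.argsort(ids, kind="stable"))
    pairs = set()
    if d2 is not None:
        np.fill_diagonal(d2, np.inf)
        for u in range(n):
            order = np.lexsort((id_rank, d2[u]))
            for v in order[:k]:
                pairs.add((min(u, v), max(u, v)))
    else:
        tree = cKDTree(xy)
        dist, idx = tree.query(xy, k=min(k + 1, n))
        for u in range(n):
            cand_d, cand_i = dist[u], idx[u]
            keep = cand_i != u
            cand_d, cand_i = cand_d[keep], cand_i[keep]
            order = np.lexsort((id_rank[cand_i], cand_d))
            for v in cand_i[order[:k]]:
                pairs.add((min(u, int(v)), max(u, int(v))))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.array(sorted(pairs), dtype=int)


def build_graph(cells: CellTable, region_id: str | None = None, mode: str = "knn",
                k: int = 6, contact_radius: float = 15.0) -> CellGraph:
    """Build the spatial neighborhood graph for one region.

    ``knn`` mode connects each cell to its k nearest neighbors (Euclidean,
    default k=6) and symmetrizes by union; ``contact`` mode connects all
    pairs within ``contact_radius`` μm of each other (centroid-distance
    approximation of touching cells).
    """
    region = cells.region(region_id) if region_id is not None else cells
    n = len(region)
    if n < 2:
        raise ValueError("graph construction needs at least 2 cells in the region")
    xy = region.xy
    ids = region.df["cell_id"].to_numpy(str)
    if mode == "knn":
        if k < 1:
            raise ValueError("k must be >= 1")
        if k >= n:
            warnings.warn(f"k={k} >= region size {n}; graph is complete", stacklevel=2)
            k = n - 1
        edges = _knn_edges(xy, ids, k)
        return CellGraph(nodes=ids, edges=edges, mode="knn", k=k)
    if mode == "contact":
        if not (contact_radius > 0):
            raise ValueError("contact_radius must be > 0")
        tree = cKDTree(xy)
        pairs = tree.query_pairs(contact_radius, output_type="ndarray")
        pairs = np.sort(pairs, axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0])) if len(pairs) else []
        edges = pairs[order] if len(pairs) else np.empty((0, 2), dtype=int)
        return CellGraph(nodes=ids, edges=edges, mode="contact", contact_radius=contact_radius)
    raise ValueError(f"unknown graph mode {mode!r}")


def nearest_distances(cells: CellTable, region_id: str | None, source_pop: str,
                      target_pop: str) -> np.ndarray:
    """Per source-cell distance (μm) to the nearest target-population cell.

    Self-pairs are excluded when source and target populations coincide.
    Returns one value per source cell; NaN (with a warning) where the target
    population is empty or reduces to the source cell itself.
    """
    region = cells.region(region_id) if region_id is not None else cells
    labels = region.labels
    src = np.flatnonzero(labels == source_pop)
    tgt = np.flatnonzero(labels == target_pop)
    if len(src) == 0:
        raise ValueError(f"source population {source_pop!r} empty in region")
    if len(tgt) == 0 or (source_pop == target_pop and len(tgt) == 1):
        warnings.warn(f"target population {target_pop!r} has no eligible cells; "
                      "distances undefined", stacklevel=2)
        return np.full(len(src), np.nan)
    xy = region.xy
    tree = cKDTree(xy[tgt])
    if source_pop == target_pop:
        d, _ = tree.query(xy[src], k=2)
        return d[:, 1]
    d, _ = tree.query(xy[src], k=1)
    return np.asarray(d, dtype=float)
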