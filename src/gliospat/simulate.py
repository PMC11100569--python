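"""Synthetic tissue, spot and cohort generators.

Every generator is a pure function of its config plus a seed, and emits
objects that satisfy the invariants of the analysis modules directly:

* :func:`simulate_region` — labeled cell point patterns in a rectangular
  region (μm): complete spatial randomness, Thomas-process homotypic
  clustering (Poisson parents, Gaussian-dispersed offspring), vessel-biased
  and hypoxia-biased placement; vascular skeletons rendered as cell chains;
  hypoxia and fibrinogen marker rasters at 1 μm/pixel; per-cell marker
  intensities as population archetypes plus truncated Gaussian noise.
* :func:`simulate_spots` — hex-grid spot datasets with planted environment
  domains, per-environment population mixtures, and counts assembled from
  population signatures plus environment-specific non-myeloid gene boosts
  under a negative-binomial noise model.
* :func:`simulate_cohort` — survival cohorts whose hazard depends
  log-linearly on planted environment proportions, with calibrated uniform
  censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .niches import SpotDataset, SurvivalCohort, make_spot_dataset
from .tissue import CellTable, MarkerRaster

__all__ = [
    "PopulationSpec",
    "VesselSpec",
    "RasterSpec",
    "TissueConfig",
    "SpotSimConfig",
    "simulate_region",
    "simulate_study",
    "simulate_spots",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """One cell population: label, expected count and placement model."""

    label: str
    n_expected: float
    placement: str = "csr"        # csr | thomas | vessel | hypoxia
    # thomas parameters
    parent_intensity: float = 20e-6   # parents per μm² (20 per mm²)
    offspring_mu: float = 30.0
    sigma: float = 30.0               # offspring dispersion, μm
    # vessel-biased
    decay_um: float = 20.0
    # hypoxia-biased
    hypoxia_weight: float = 4.0


@dataclass
class VesselSpec:
    n_segments: int = 6
    length_um: float = 400.0
    width_um: float = 10.0
    cell_spacing_um: float = 8.0
    leaky_fraction: float = 0.5       # fraction of segments with fibrinogen leak


@dataclass
class RasterSpec:
    scale: float = 1.0                # μm per pixel
    baseline: float = 0.05
    hypoxia_amplitude: float = 0.8
    hypoxia_length_um: float = 150.0
    noise_sd: float = 0.05
    fibrinogen_vessel: float = 0.9
    fibrinogen_leak: float = 0.6
    leak_sigma_um: float = 40.0


@dataclass
class TissueConfig:
    """Study conditions for one synthetic region (defaults: 1 mm² ROI)."""

    width_um: float = 1000.0
    height_um: float = 1000.0
    populations: list[PopulationSpec] = field(default_factory=list)
    vessels: VesselSpec = field(default_factory=VesselSpec)
    raster: RasterSpec = field(default_factory=RasterSpec)
    marker_noise_sd: float = 0.1
    seed: int = 0
    case_id: str = "case1"
    region_id: str = "r1"
    region_class: str = "edge"

    def __post_init__(self):
        if not self.populations:
            self.populations = [
                PopulationSpec("PopA", 400, "thomas"),
                PopulationSpec("PopB", 400, "thomas"),
                PopulationSpec("PopC", 400, "csr"),
            ]
        for p in self.populations:
            if p.n_expected <= 0:
                raise ValueError(f"population {p.label!r} has non-positive count")


@dataclass
class SpotSimConfig:
    """Planted-environment spot dataset (defaults: 5 environments, ~500 spots)."""

    n_cols: int = 25
    n_rows: int = 20
    n_environments: int = 5
    populations: tuple[str, ...] = ("Mg", "TAM-Mac", "TAM-Supp", "TAM-Int", "Mono")
    abundance_scale: float = 10.0
    abundance_noise_sd: float = 1.0     # 0.1 × archetype scale
    n_marker_genes_per_pop: int = 10
    n_deg_per_env: int = 8
    deg_fold: float = 3.0
    n_housekeeping: int = 60
    base_rate: float = 2.0
    nb_dispersion: float = 0.5
    library_mu_log: float = np.log(5000.0)
    library_sigma_log: float = 0.35
    low_library_fraction: float = 0.0   # fraction forced below the QC cut
    seed: int = 0


# ---------------------------------------------------------------------------
# region generator
# ---------------------------------------------------------------------------

def _vessel_segments(cfg: TissueConfig, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    segs = []
    v = cfg.vessels
    for s in range(v.n_segments):
        p0 = rng.uniform([0, 0], [cfg.width_um, cfg.height_um])
        ang = rng.uniform(0, 2 * np.pi)
        p1 = p0 + v.length_um * np.array([np.cos(ang), np.sin(ang)])
        p1 = np.clip(p1, 0, [cfg.width_um, cfg.height_um])
        leaky = rng.random() < v.leaky_fraction
        segs.append((p0, p1, leaky))
    return segs


def _points_on_segments(segs, spacing: float, rng: np.random.Generator) -> np.ndarray:
    pts = []
    for p0, p1, _ in segs:
        length = float(np.linalg.norm(p1 - p0))
        n = max(2, int(length / spacing))
        t = np.linspace(0, 1, n)
        xy = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        xy = xy + rng.normal(0, spacing / 6, xy.shape)
        pts.append(xy)
    return np.vstack(pts) if pts else np.empty((0, 2))


def _vessel_distance_grid(segs, cfg: TissueConfig) -> np.ndarray:
    """Distance (μm) from each pixel center to the nearest vessel centerline."""
    s = cfg.raster.scale
    h, w = int(round(cfg.height_um / s)), int(round(cfg.width_um / s))
    mask = np.ones((h, w), dtype=bool)
    for p0, p1, _ in segs:
        length = float(np.linalg.norm(p1 - p0))
        n = max(2, int(length / (0.5 * s)))
        t = np.linspace(0, 1, n)
        xy = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        jj = np.clip((xy[:, 0] / s - 0.5).round().astype(int), 0, w - 1)
        ii = np.clip((xy[:, 1] / s - 0.5).round().astype(int), 0, h - 1)
        mask[ii, jj] = False
    return distance_transform_edt(mask, sampling=s)


def _hypoxia_grid(vessel_dist: np.ndarray, cfg: TissueConfig,
                  rng: np.random.Generator) -> np.ndarray:
    r = cfg.raster
    base = vessel_dist / (vessel_dist + r.hypoxia_length_um)   # 0 at vessels → 1 far
    noise = gaussian_filter(rng.standard_normal(vessel_dist.shape),
                            sigma=r.hypoxia_length_um / (4 * r.scale))
    sd = noise.std()
    if sd > 0:
        noise = noise / sd * r.noise_sd
    return np.clip(r.baseline + r.hypoxia_amplitude * base + noise, 0, None)


def _fibrinogen_grid(vessel_dist: np.ndarray, segs, cfg: TissueConfig,
                     rng: np.random.Generator) -> np.ndarray:
    r = cfg.raster
    v = cfg.vessels
    grid = r.baseline + r.fibrinogen_vessel * np.exp(-vessel_dist / max(v.width_um, 1e-9))
    h, w = grid.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (xx + 0.5) * r.scale, (yy + 0.5) * r.scale
    for p0, p1, leaky in segs:
        if not leaky:
            continue
        mid = 0.5 * (p0 + p1) + rng.normal(0, v.width_um, 2)
        d2 = (cx - mid[0]) ** 2 + (cy - mid[1]) ** 2
        grid = grid + r.fibrinogen_leak * np.exp(-d2 / (2 * r.leak_sigma_um ** 2))
    grid = grid + rng.normal(0, r.noise_sd, grid.shape)
    return np.clip(grid, 0, None)


def _sample_weighted(n: int, weight_fn, cfg: TissueConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points with acceptance ∝ weight_fn(xy) ∈ (0, 1]."""
    out = []
    got = 0
    while got < n:
        m = max(4 * (n - got), 64)
        cand = rng.uniform([0, 0], [cfg.width_um, cfg.height_um], size=(m, 2))
        wts = weight_fn(cand)
        keep = cand[rng.random(m) < wts]
        out.append(keep)
        got += len(keep)
    return np.vstack(out)[:n]


def _place_population(pop: PopulationSpec, cfg: TissueConfig, rng: np.random.Generator,
                      vessel_dist_at, hypoxia_at) -> np.ndarray:
    area = cfg.width_um * cfg.height_um
    lo = np.array([0.0, 0.0])
    hi = np.array([cfg.width_um, cfg.height_um])
    if pop.placement == "csr":
        n = rng.poisson(pop.n_expected)
        return rng.uniform(lo, hi, size=(n, 2))
    if pop.placement == "thomas":
        n_parents = rng.poisson(pop.parent_intensity * area)
        if n_parents == 0:
            n_parents = 1
        parents = rng.uniform(lo, hi, size=(n_parents, 2))
        mu = pop.n_expected / n_parents
        pts = []
        for p in parents:
            m = rng.poisson(mu)
            if m:
                pts.append(p[None, :] + rng.normal(0, pop.sigma, (m, 2)))
        if not pts:
            return np.empty((0, 2))
        xy = np.vstack(pts)
        inside = (xy >= lo).all(1) & (xy <= hi).all(1)
        return xy[inside]
    if pop.placement == "vessel":
        n = rng.poisson(pop.n_expected)
        return _sample_weighted(n, lambda c: np.exp(-vessel_dist_at(c) / pop.decay_um),
                                cfg, rng)
    if pop.placement == "hypoxia":
        n = rng.poisson(pop.n_expected)

        def w(c):
            hz = hypoxia_at(c)
            v = np.exp(pop.hypoxia_weight * hz)
            return v / v.max() if len(v) else v

        return _sample_weighted(n, w, cfg, rng)
    raise ValueError(f"unknown placement {pop.placement!r}")


def simulate_region(config: TissueConfig) -> tuple[CellTable, dict[str, MarkerRaster]]:
    """Generate one labeled region plus its hypoxia/fibrinogen rasters.

    Returns the cell table (with per-cell marker intensities, including the
    population archetype markers ``m_<label>``) and rasters keyed by channel
    name (``hypoxia``, ``fibrinogen``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1]))
    segs = _vessel_segments(config, rng)
    vdist = _vessel_distance_grid(segs, config)
    hyp = _hypoxia_grid(vdist, config, rng)
    fib = _fibrinogen_grid(vdist, segs, config, rng)
    s = config.raster.scale
    h, w = vdist.shape

    def grid_at(grid, c):
        jj = np.clip((c[:, 0] / s - 0.5).round().astype(int), 0, w - 1)
        ii = np.clip((c[:, 1] / s - 0.5).round().astype(int), 0, h - 1)
        return grid[ii, jj]

    rows = []
    vessel_xy = _points_on_segments(segs, config.vessels.cell_spacing_um, rng)
    vessel_xy = np.clip(vessel_xy, 0, [config.width_um, config.height_um])
    for x, y in vessel_xy:
        rows.append(("Vascular", x, y))
    for pop in config.populations:
        xy = _place_population(pop, config, rng,
                               lambda c: grid_at(vdist, c), lambda c: grid_at(hyp, c))
        for x, y in xy:
            rows.append((pop.label, x, y))
    if not rows:
        raise ValueError("configuration produced zero cells")
    labels = np.array([r[0] for r in rows])
    xy = np.array([(r[1], r[2]) for r in rows], dtype=float)
    pop_names = ["Vascular"] + [p.label for p in config.populations]
    # archetype markers: one channel per population, high in that population
    markers = {}
    for p in pop_names:
        arch = np.where(labels == p, 0.8, 0.1)
        vals = arch + rng.normal(0, config.marker_noise_sd, len(labels))
        markers[f"m_{p}"] = np.clip(vals, 0, None)
    df = pd.DataFrame({
        "cell_id": [f"{config.region_id}_c{i}" for i in range(len(labels))],
        "x": xy[:, 0], "y": xy[:, 1],
        "case_id": config.case_id, "region_id": config.region_id,
        "region_class": config.region_class, "population": labels,
        **markers,
    })
    cells = CellTable(df, marker_cols=list(markers), populations=sorted(pop_names))
    rasters = {
        "hypoxia": MarkerRaster("hypoxia", hyp, scale=s),
        "fibrinogen": MarkerRaster("fibrinogen", fib, scale=s),
    }
    return cells, rasters


def simulate_study(seed: int = 0, n_cases: int = 2, regions_per_case: int = 3,
                   base_config: TissueConfig | None = None
                   ) -> tuple[CellTable, dict[tuple[str, str], dict[str, MarkerRaster]]]:
    """Multi-case, multi-region synthetic study (edge/core alternating)."""
    from dataclasses import replace

    tables = []
    rasters: dict[tuple[str, str], dict[str, MarkerRaster]] = {}
    base = base_config or TissueConfig()
    idx = 0
    for c in range(n_cases):
        for r in range(regions_per_case):
            cfg = replace(base,
                          seed=(seed * 1000 + idx) & 0x7FFFFFFF,
                          case_id=f"case{c + 1}",
                          region_id=f"case{c + 1}_r{r + 1}",
                          region_class="edge" if r % 2 == 0 else "core")
            cells, rast = simulate_region(cfg)
            tables.append(cells.df)
            rasters[(cfg.case_id, cfg.region_id)] = rast
            idx += 1
    df = pd.concat(tables, ignore_index=True)
    pops = sorted(df["population"].unique())
    marker_cols = [c for c in tables[0].columns if c.startswith("m_")]
    return CellTable(df, marker_cols=marker_cols, populations=pops), rasters


# ---------------------------------------------------------------------------
# spot generator
# ---------------------------------------------------------------------------

def _planted_environment_map(cfg: SpotSimConfig) -> np.ndarray:
    """Contiguous vertical bands of environments across the hex grid."""
    cols = np.repeat(np.arange(cfg.n_cols), cfg.n_rows)
    band = (cols * cfg.n_environments) // cfg.n_cols
    return band.astype(int)


def simulate_spots(cfg: SpotSimConfig) -> tuple[SpotDataset, dict]:
    """Hex-grid spot dataset with planted environments, mixtures and DEGs.

    Counts are negative-binomial draws around rate = signaturesᵀ·abundance
    (+ environment-specific boosts of the planted non-myeloid DEGs), scaled
    to a log-normal library size.  Returns the dataset plus the planted
    truth: environment map, per-environment DEG lists, mixtures and the
    populations×genes reference signature matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 2]))
    n_spots = cfg.n_cols * cfg.n_rows
    n_pop = len(cfg.populations)
    env_map = _planted_environment_map(cfg)

    # per-environment population mixtures: each environment dominated by a
    # rotating subset of populations
    mixtures = np.full((cfg.n_environments, n_pop), 0.4)
    for e in range(cfg.n_environments):
        mixtures[e, e % n_pop] = 3.0
        mixtures[e, (e + 1) % n_pop] = 1.5
    if (mixtures <= 0).all(axis=1).any():
        raise ValueError("degenerate all-zero mixture")
    abundance = mixtures[env_map] * cfg.abundance_scale / mixtures.sum(1, keepdims=True)[env_map]
    abundance = np.clip(abundance + rng.normal(0, cfg.abundance_noise_sd,
                                               abundance.shape), 0, None)

    # genes: myeloid marker genes (population-specific), env DEGs, housekeeping
    genes, gene_kind = [], []
    for pi, p in enumerate(cfg.populations):
        for g in range(cfg.n_marker_genes_per_pop):
            genes.append(f"MYE-{p}-{g}")
            gene_kind.append(("pop", pi))
    deg_truth: dict[int, list[str]] = {e: [] for e in range(cfg.n_environments)}
    for e in range(cfg.n_environments):
        for g in range(cfg.n_deg_per_env):
            name = f"ENVG-{e}-{g}"
            genes.append(name)
            gene_kind.append(("deg", e))
            deg_truth[e].append(name)
    for g in range(cfg.n_housekeeping):
        genes.append(f"HK-{g}")
        gene_kind.append(("hk", -1))
    genes += ["MT-CO1", "MT-ND1"]
    gene_kind += [("mito", -1), ("mito", -1)]
    n_genes = len(genes)

    # reference signatures on the counts scale (per-population mean profile)
    signatures = np.zeros((n_pop, n_genes))
    for gi, (kind, which) in enumerate(gene_kind):
        if kind == "pop":
            signatures[:, gi] = 0.05
            signatures[which, gi] = 2.0
        else:
            signatures[:, gi] = 0.05        # identical across populations

    rate = abundance @ signatures * cfg.base_rate        # spots × genes
    for gi, (kind, which) in enumerate(gene_kind):
        if kind == "hk":
            rate[:, gi] += cfg.base_rate
        elif kind == "mito":
            rate[:, gi] += 2 * cfg.base_rate
        elif kind == "deg":
            rate[:, gi] += cfg.base_rate
            rate[env_map == which, gi] *= cfg.deg_fold

    lib = rng.lognormal(cfg.library_mu_log, cfg.library_sigma_log, n_spots)
    if cfg.low_library_fraction > 0:
        n_low = int(round(cfg.low_library_fraction * n_spots))
        low_idx = rng.choice(n_spots, size=n_low, replace=False)
        lib[low_idx] = rng.uniform(100, 900, n_low)
    rate = rate / rate.sum(1, keepdims=True) * lib[:, None]
    # negative binomial via gamma-Poisson mixture; dispersion r = 1/alpha
    alpha = cfg.nb_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * rate)
    else:
        lam = rate
    counts = rng.poisson(lam)

    cols = np.repeat(np.arange(cfg.n_cols), cfg.n_rows)
    rows_ = np.tile(np.arange(cfg.n_rows), cfg.n_cols)
    spot_ids = [f"spot_{i}" for i in range(n_spots)]
    pitch = 100.0
    coords = pd.DataFrame({
        "hex_col": cols, "hex_row": rows_,
        "x_um": (cols + 0.5 * rows_) * pitch,
        "y_um": rows_ * pitch * np.sqrt(3) / 2,
    }, index=spot_ids)
    counts_df = pd.DataFrame(counts, index=spot_ids, columns=genes)
    abund_df = pd.DataFrame(abundance, index=spot_ids, columns=list(cfg.populations))
    ds = make_spot_dataset(counts_df, coords, abund_df)
    truth = {
        "environment": pd.Series(env_map, index=spot_ids),
        "degs": deg_truth,
        "mixtures": pd.DataFrame(mixtures, columns=list(cfg.populations)),
        "signatures": pd.DataFrame(signatures, index=list(cfg.populations),
                                   columns=genes),
        "library_sizes": pd.Series(lib, index=spot_ids),
    }
    return ds, truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def simulate_cohort(n: int, betas, censor_frac: float = 0.2, seed: int = 0,
                    baseline_rate: float = 1.0 / 12.0,
                    dirichlet_alpha: float = 2.0) -> tuple[SurvivalCohort, dict]:
    """Cohort with hazard log-linear in environment proportions.

    ``betas`` are log hazard ratios per percentage point of each
    environment's proportion; proportions are symmetric-Dirichlet on the
    simplex; event times are exponential with rate
    λ₀·exp(Σ βₖ·100·propₖ); censoring is independent uniform on (0, c_max)
    with c_max calibrated so the realized censored fraction matches
    ``censor_frac``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= censor_frac < 1):
        raise ValueError("censor_frac must be in [0, 1)")
    betas = np.asarray(betas, float)
    k = len(betas)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 3]))
    props = rng.dirichlet(np.full(k, dirichlet_alpha), size=n)
    lin = props @ (betas * 100.0)
    rate = baseline_rate * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    if censor_frac == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        u = rng.random(n)

        def realized(cmax):
            c = u * cmax
            return float(np.mean(c < t_event))

        lo, hi = 1e-6, float(t_event.max()) * 4 + 1.0
        while realized(hi) > censor_frac and hi < 1e9:
            hi *= 4
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if realized(mid) > censor_frac:
                lo = mid
            else:
                hi = mid
        cmax = 0.5 * (lo + hi)
        c = u * cmax
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    env_cols = [f"env_{i}" for i in range(k)]
    df = pd.DataFrame(props, columns=env_cols)
    df.insert(0, "sample_id", [f"s{i}" for i in range(n)])
    df["time"] = np.maximum(time, 1e-6)
    df["event"] = event
    cohort = SurvivalCohort(df, env_cols=env_cols)
    truth = {"betas_per_pct": betas, "proportions": props,
             "censor_frac_realized": float(1 - event.mean())}
    return cohort, truth
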