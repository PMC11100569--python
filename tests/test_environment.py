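"""Rao entropy, window expression, cross-PCF, vascular classes, nested models."""

import numpy as np
import pandas as pd
import pytest

from gliospat.environment import (
    cross_pcf,
    holm_sidak,
    infiltration_rate,
    nested_compare,
    rao_entropy,
    rao_entropy_all,
    vascular_classes,
    window_expression,
)
from gliospat.tissue import CellGraph, MarkerRaster, build_graph

from .conftest import csr_cells, make_cells


def _contact_graph(n, edges):
    return CellGraph(nodes=np.array([f"n{i}" for i in range(n)]),
                     edges=np.array(edges, dtype=int).reshape(-1, 2),
                     mode="contact", contact_radius=15.0)


# ---------------------------------------------------------------------------
# Rao entropy
# ---------------------------------------------------------------------------

def test_rao_zero_for_identical_phenotypes():
    g = _contact_graph(3, [(0, 1), (0, 2)])
    pheno = np.ones((3, 4)) * 0.3
    assert rao_entropy(0, g, pheno) == 0.0


def test_rao_two_cell_closed_form():
    g = _contact_graph(2, [(0, 1)])
    pheno = np.array([[0.0, 0.0], [0.3, 0.4]])   # distance 0.5
    assert rao_entropy(0, g, pheno) == pytest.approx(0.25)  # d/2


def test_rao_matches_pairwise_double_sum():
    rng = np.random.default_rng(4)
    g = _contact_graph(6, [(0, i) for i in range(1, 6)])
    pheno = rng.random((6, 5))
    hood = np.arange(6)
    m = len(hood)
    want = sum(np.linalg.norm(pheno[i] - pheno[j]) / m ** 2
               for i in hood for j in hood)
    assert rao_entropy(0, g, pheno) == pytest.approx(want, abs=1e-9)


def test_rao_isolated_cell_flagged_zero():
    g = _contact_graph(2, [])
    g.edges = np.empty((0, 2), dtype=int)
    with pytest.warns(UserWarning, match="no contacts"):
        assert rao_entropy(0, g, np.random.rand(2, 3)) == 0.0


def test_rao_invariances():
    rng = np.random.default_rng(5)
    pheno = rng.random((5, 3))
    g1 = _contact_graph(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
    q = rao_entropy(0, g1, pheno)
    # neighbor order cannot matter: same edges listed differently
    g2 = _contact_graph(5, [(0, 4), (0, 3), (0, 2), (0, 1)])
    assert rao_entropy(0, g2, pheno) == pytest.approx(q, abs=1e-12)
    dmax = max(np.linalg.norm(pheno[i] - pheno[j]) for i in range(5) for j in range(5))
    assert q <= dmax
    all_q = rao_entropy_all(g1, pheno)
    assert all_q[0] == pytest.approx(q, abs=1e-12)


# ---------------------------------------------------------------------------
# window expression
# ---------------------------------------------------------------------------

def test_window_constant_raster():
    cells = make_cells([(50, 50), (10, 90)], "AA")
    raster = MarkerRaster("m", np.full((100, 100), 3.25))
    np.testing.assert_allclose(window_expression(cells, raster, 40.0), 3.25)


def test_window_corner_clipping():
    grid = np.zeros((100, 100))
    grid[:20, :20] = 2.0          # hot quadrant at origin
    cells = make_cells([(0.0, 0.0)], "A")
    raster = MarkerRaster("m", grid)
    # window clipped to the 20x20 in-bounds quadrant -> mean of hot pixels only
    got = window_expression(cells, raster, 40.0)
    assert got[0] == pytest.approx(2.0)


def test_window_single_hot_pixel():
    grid = np.zeros((200, 200))
    grid[100, 100] = 1600.0       # pixel center (100.5, 100.5)
    cells = make_cells([(100.0, 100.0)], "A")
    raster = MarkerRaster("m", grid)
    got = window_expression(cells, raster, 40.0)
    assert got[0] == pytest.approx(1600.0 / 1600.0)   # 40x40 window at 1 um/px


def test_window_matches_brute_force_pixel_scan():
    rng = np.random.default_rng(6)
    grid = rng.random((64, 64))
    raster = MarkerRaster("m", grid, scale=1.0)
    cells = make_cells(rng.uniform(0, 64, (20, 2)), ["A"] * 20)
    for shape in ("square", "disc"):
        got = window_expression(cells, raster, 17.0, shape=shape)
        for c, (cx, cy) in enumerate(cells.xy):
            vals = []
            for i in range(64):
                for j in range(64):
                    px, py = j + 0.5, i + 0.5
                    if shape == "square":
                        inside = abs(px - cx) <= 8.5 and abs(py - cy) <= 8.5
                    else:
                        inside = (px - cx) ** 2 + (py - cy) ** 2 <= 8.5 ** 2
                    if inside:
                        vals.append(grid[i, j])
            assert got[c] == pytest.approx(np.mean(vals), abs=1e-9)


def test_window_out_of_bounds_flagged():
    raster = MarkerRaster("m", np.ones((50, 50)))
    cells = make_cells([(500.0, 500.0)], "A")
    with pytest.warns(UserWarning, match="no pixel centers"):
        got = window_expression(cells, raster, 10.0)
    assert np.isnan(got[0])


# ---------------------------------------------------------------------------
# cross-PCF
# ---------------------------------------------------------------------------

def test_cross_pcf_empty_population_flagged():
    cells = csr_cells(50, n_pop=2, seed=1)
    with pytest.warns(UserWarning, match="undefined"):
        res = cross_pcf(cells, "A", "Z", n_perm=10, seed=0)
    assert not res.defined and np.isnan(res.observed)


def test_cross_pcf_csr_near_zero():
    cells = csr_cells(800, n_pop=2, size=1000.0, seed=7)
    res = cross_pcf(cells, "A", "B", radius_um=20.0, n_perm=100, seed=1)
    assert abs(res.diff) < 4 * res.null_sd * np.sqrt(1 + 1 / 100)
    assert 0 < res.p_value <= 1


def test_cross_pcf_coclustered_positive_and_significant():
    rng = np.random.default_rng(9)
    centers = rng.uniform(0, 800, (6, 2))
    a = centers[rng.integers(0, 6, 120)] + rng.normal(0, 15, (120, 2))
    b = centers[rng.integers(0, 6, 120)] + rng.normal(0, 15, (120, 2))
    c = rng.uniform(0, 800, (200, 2))
    cells = make_cells(np.vstack([a, b, c]),
                       ["A"] * 120 + ["B"] * 120 + ["C"] * 200)
    res = cross_pcf(cells, "A", "B", radius_um=20.0, n_perm=300, seed=2)
    assert res.diff > 0 and res.p_value <= 0.01


# ---------------------------------------------------------------------------
# vascular classes
# ---------------------------------------------------------------------------

def test_vascular_threshold_classes():
    cells = make_cells([(0, 0), (0, 0), (5, 0), (15, 0)],
                       ["Vasc", "X", "X", "X"])
    out = vascular_classes(cells, "Vasc", near_um=0.0, far_um=10.0)
    assert list(out["vascular_class"]) == ["vascular", "vascular",
                                           "perivascular", "infiltrated"]
    assert out["distance_to_vessel"].tolist() == [0.0, 0.0, 5.0, 15.0]


def test_vascular_classes_match_brute_force():
    cells = csr_cells(200, n_pop=3, size=300.0, seed=12)
    labels = cells.labels.copy()
    out = vascular_classes(cells, "A", near_um=0.0, far_um=10.0)
    xy = cells.xy
    v_idx = np.flatnonzero(labels == "A")
    for i in range(200):
        d = 0.0 if labels[i] == "A" else min(np.hypot(*(xy[i] - xy[j])) for j in v_idx)
        assert out["distance_to_vessel"].iloc[i] == pytest.approx(d, abs=1e-9)
        want = "vascular" if d <= 0 else ("perivascular" if d <= 10 else "infiltrated")
        assert out["vascular_class"].iloc[i] == want
    # class proportions sum to 1 over classified cells
    props = out["vascular_class"].value_counts(normalize=True)
    assert props.sum() == pytest.approx(1.0)


def test_vascular_no_vessels_warns():
    cells = csr_cells(20, n_pop=2, seed=2)
    with pytest.warns(UserWarning, match="no vascular"):
        out = vascular_classes(cells, "Z")
    assert out["distance_to_vessel"].isna().all()
    assert np.isnan(infiltration_rate(out))


# ---------------------------------------------------------------------------
# nested comparison
# ---------------------------------------------------------------------------

def _nested_df(rng, shift=0.0, n_cases=6, n_regions=3, n_cells=30):
    rows = []
    for c in range(n_cases):
        case_eff = rng.normal(0, 0.5)
        for r in range(n_regions):
            reg_eff = rng.normal(0, 0.3)
            for pop, s in (("A", 0.0), ("B", shift)):
                for _ in range(n_cells):
                    rows.append({"case_id": f"c{c}", "region_id": f"c{c}r{r}",
                                 "population": pop,
                                 "value": case_eff + reg_eff + s + rng.normal()})
    return pd.DataFrame(rows)


def test_holm_sidak_ladder_closed_form():
    k = 4
    adj = holm_sidak([0.02] * k)
    want = [1 - (1 - 0.02) ** (k - i) for i in range(k)]
    # step-down with equal raw p: all get the first (largest) correction
    np.testing.assert_allclose(adj, max(want), atol=1e-12)


def test_nested_compare_detects_planted_shift():
    df = _nested_df(np.random.default_rng(1), shift=1.0)
    res = nested_compare(df)
    assert res.method == "lmm" and res.converged
    est = res.contrasts["estimate"].iloc[0]
    assert est == pytest.approx(1.0, abs=0.25)
    assert res.contrasts["p_adj"].iloc[0] < 0.01


def test_nested_compare_type_one_error_rate():
    # no true difference: rejection rate stays near the nominal level
    rng = np.random.default_rng(42)
    rejections = 0
    n_sim = 200
    for _ in range(n_sim):
        df = _nested_df(rng, shift=0.0, n_cases=10, n_regions=3, n_cells=50)
        res = nested_compare(df)
        rejections += int((res.p_adj < 0.05).any())
    assert rejections / n_sim <= 0.07


def test_nested_compare_power_for_one_sd_shift():
    rng = np.random.default_rng(43)
    detected = 0
    n_sim = 200
    for _ in range(n_sim):
        df = _nested_df(rng, shift=1.0, n_cases=10, n_regions=3, n_cells=50)
        res = nested_compare(df)
        detected += int((res.p_adj < 0.05).all())
    assert detected / n_sim >= 0.90


def test_nested_compare_single_region_per_case_flagged():
    df = _nested_df(np.random.default_rng(3), shift=0.5, n_regions=1)
    res = nested_compare(df)
    assert any("single region" in f for f in res.flags)
    assert res.method in ("lmm_case_only", "wilcoxon_fallback")
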