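"""Spot QC/normalization, signature scoring, environment clustering, survival."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gliospat.niches import (
    SurvivalCohort,
    cluster_environments,
    correlate_factors,
    environment_connectivity,
    environment_markers,
    hex_neighbor_edges,
    make_spot_dataset,
    nonmyeloid_signature,
    qc_normalize,
    score_signature,
    survival_association,
)
from gliospat.simulate import simulate_cohort


def _tiny_dataset(counts, n_pop=2):
    counts = pd.DataFrame(counts)
    counts.index = [f"s{i}" for i in range(len(counts))]
    counts.columns = [f"g{j}" for j in range(counts.shape[1])] \
        if not isinstance(counts.columns[0], str) else counts.columns
    n = len(counts)
    side = int(np.ceil(np.sqrt(n)))
    coords = pd.DataFrame({"hex_col": [i % side for i in range(n)],
                           "hex_row": [i // side for i in range(n)]},
                          index=counts.index)
    abund = pd.DataFrame(np.ones((n, n_pop)),
                         columns=[f"p{k}" for k in range(n_pop)],
                         index=counts.index)
    return make_spot_dataset(counts, coords, abund)


# ---------------------------------------------------------------------------
# QC + normalization
# ---------------------------------------------------------------------------

def test_qc_count_boundary():
    ds = _tiny_dataset({"g0": [999, 1000, 1500], "g1": [0, 0, 0]})
    out = qc_normalize(ds, min_counts=1000)
    assert out.n_spots == 2                      # 999 dropped, 1000 kept
    assert out.adata.uns["qc"]["n_spots_removed"] == 1


def test_qc_removes_mitochondrial_genes():
    ds = _tiny_dataset({"g0": [2000, 2000], "MT-CO1": [5, 5], "MT-ND1": [3, 3]})
    out = qc_normalize(ds, min_counts=1000, mito_prefixes=("MT-",))
    assert out.genes == ["g0"]
    assert out.adata.uns["qc"]["n_genes_removed"] == 2


def test_normalization_library_size_invariance():
    # proportional count vectors normalize to identical expression
    ds = _tiny_dataset({"g0": [1000, 3000], "g1": [2000, 6000], "g2": [1000, 3000]})
    out = qc_normalize(ds, min_counts=100)
    np.testing.assert_allclose(out.expression[0], out.expression[1], atol=1e-9)


def test_normalization_monotone_within_spot():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 200, (4, 30))
    counts[:, 0] += 2000
    ds = _tiny_dataset(pd.DataFrame(counts))
    out = qc_normalize(ds, min_counts=100)
    for s in range(out.n_spots):
        order_counts = np.argsort(out.counts[s], kind="stable")
        expr_sorted = out.expression[s][order_counts]
        assert (np.diff(expr_sorted) >= -1e-12).all()


def test_qc_all_spots_fail_raises():
    ds = _tiny_dataset({"g0": [1, 2]})
    with pytest.raises(ValueError, match="QC"):
        qc_normalize(ds, min_counts=1000)


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------

def test_score_signature_disjoint_set_errors():
    ds = _tiny_dataset(pd.DataFrame(np.ones((2, 10), dtype=int) * 300))
    ds = qc_normalize(ds, min_counts=100)
    with pytest.raises(ValueError, match="no overlap"):
        score_signature(ds, ["absent1", "absent2"])


def test_score_signature_matches_combinatorial_enumeration():
    # universe of 20 genes, top 5 selected, set of 4 with known overlap
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(50, 100, (3, 20)),
                          columns=[f"g{j:02d}" for j in range(20)])
    # spot 0: make genes g00..g04 clearly the top 5, overlap 3 with the set
    counts.iloc[0, :5] = [5000, 4000, 3000, 2000, 1000]
    ds = qc_normalize(_tiny_dataset(counts), min_counts=100)
    gene_set = ["g00", "g01", "g02", "g10"]
    scores = score_signature(ds, gene_set, top_fraction=0.25)

    def hyper_tail(k, n_univ, big_k, n_sel):
        def comb(a, b):
            return math.comb(a, b) if 0 <= b <= a else 0
        return sum(comb(big_k, x) * comb(n_univ - big_k, n_sel - x)
                   for x in range(k, min(big_k, n_sel) + 1)) / comb(n_univ, n_sel)

    want = -math.log10(hyper_tail(3, 20, 4, 5))
    assert scores[0] == pytest.approx(want, abs=1e-9)
    assert (scores >= 0).all()


def test_score_signature_monotone_in_overlap():
    # larger overlap at fixed margins never decreases the score
    rng = np.random.default_rng(4)
    base = rng.integers(50, 60, (2, 20))
    counts = pd.DataFrame(base, columns=[f"g{j:02d}" for j in range(20)])
    counts.iloc[0, [0, 1, 2, 3, 4]] = 1000       # top-5 overlap 2 with set below
    counts.iloc[1, [0, 1, 5, 6, 7]] = 1000       # top-5 overlap 2 -> modify
    counts.iloc[0, 5] = 900
    ds = qc_normalize(_tiny_dataset(counts), min_counts=100)
    s_hi = score_signature(ds, ["g00", "g01", "g02"], top_fraction=0.25)
    s_lo = score_signature(ds, ["g10", "g11", "g12"], top_fraction=0.25)
    assert (s_hi >= s_lo - 1e-12).all()


# ---------------------------------------------------------------------------
# factor correlation screen
# ---------------------------------------------------------------------------

def test_correlate_factors_linear_and_threshold():
    rng = np.random.default_rng(5)
    abund = pd.DataFrame({"popA": rng.random(30), "popB": rng.random(30)})
    factors = pd.DataFrame({
        "linear": 2 * abund["popA"] + 1,
        "flat": np.full(30, 0.5) + rng.normal(0, 0.005, 30),   # SD < 0.05
    })
    out = correlate_factors(abund, factors, min_factor_sd=0.05)
    lin = out[(out["factor"] == "linear") & (out["population"] == "popA")]
    assert lin["r"].iloc[0] == pytest.approx(1.0, abs=1e-9)
    flat = out[out["factor"] == "flat"]
    assert flat["excluded"].all()


def test_correlate_factors_matches_closed_form():
    rng = np.random.default_rng(6)
    abund = pd.DataFrame({"p": rng.random(8)})
    factors = pd.DataFrame({"f": rng.random(8)})
    out = correlate_factors(abund, factors, min_factor_sd=0.0)
    x, y = factors["f"].to_numpy(), abund["p"].to_numpy()
    want = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert out["r"].iloc[0] == pytest.approx(want, abs=1e-9)


def test_correlate_factors_constant_abundance_flagged():
    abund = pd.DataFrame({"p": np.ones(10)})
    factors = pd.DataFrame({"f": np.arange(10.0)})
    out = correlate_factors(abund, factors)
    assert out["flag"].str.contains("constant").any()


# ---------------------------------------------------------------------------
# environment clustering + connectivity
# ---------------------------------------------------------------------------

def test_cluster_environments_recovers_planted_archetypes():
    rng = np.random.default_rng(7)
    archetypes = np.eye(5) * 10
    truth = rng.integers(0, 5, 500)
    x = archetypes[truth] + rng.normal(0, 1.0, (500, 5))   # noise 0.1x scale
    labels = cluster_environments(pd.DataFrame(x), k=5, seed=0)
    assert adjusted_rand_score(truth, labels) > 0.9


def test_cluster_environments_deterministic_and_duplicate_consistent():
    rng = np.random.default_rng(8)
    x = pd.DataFrame(rng.random((40, 3)))
    both = pd.concat([x, x], ignore_index=True)
    labels = cluster_environments(both, k=3, seed=5)
    np.testing.assert_array_equal(labels[:40], labels[40:])
    again = cluster_environments(both, k=3, seed=5)
    np.testing.assert_array_equal(labels, again)
    # renumbering: label 0 is the largest cluster
    sizes = np.bincount(labels)
    assert (np.diff(sizes) <= 0).all()


def test_cluster_environments_k_bounds():
    x = pd.DataFrame(np.random.default_rng(0).random((4, 2)))
    with pytest.raises(ValueError):
        cluster_environments(x, k=10)
    with pytest.raises(ValueError):
        cluster_environments(x, k=1)


def test_hex_interior_spot_has_six_neighbors():
    coords = np.array([(c, r) for c in range(5) for r in range(5)])
    edges = hex_neighbor_edges(coords)
    deg = np.zeros(len(coords), int)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    center = np.flatnonzero((coords[:, 0] == 2) & (coords[:, 1] == 2))[0]
    assert deg[center] == 6


def test_environment_connectivity_single_and_halfplane():
    n_col = n_row = 10
    counts = pd.DataFrame(np.full((100, 2), 600),
                          index=[f"s{i}" for i in range(100)], columns=["g0", "g1"])
    coords = pd.DataFrame({"hex_col": np.repeat(np.arange(n_col), n_row),
                           "hex_row": np.tile(np.arange(n_row), n_col)},
                          index=counts.index)
    abund = pd.DataFrame(np.ones((100, 2)), columns=["a", "b"], index=counts.index)
    ds = make_spot_dataset(counts, coords, abund)
    ds.set_environment(np.zeros(100, int))
    conn = environment_connectivity(ds)
    np.testing.assert_allclose(conn.to_numpy(), [[1.0]])
    # two half-planes: off-diagonal equals brute-force border edge count
    env = (coords["hex_col"] >= 5).astype(int).to_numpy()
    ds.set_environment(env)
    conn2 = environment_connectivity(ds)
    edges = hex_neighbor_edges(coords.to_numpy())
    cnt = np.zeros((2, 2))
    for u, v in edges:
        cnt[env[u], env[v]] += 1
        cnt[env[v], env[u]] += 1
    want = cnt / cnt.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(conn2.to_numpy(), want, atol=1e-12)
    assert np.allclose(conn2.to_numpy().sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# non-myeloid genes + markers
# ---------------------------------------------------------------------------

def test_nonmyeloid_signature_threshold():
    sig = pd.DataFrame({"flat": [1.0, 1.0, 1.0],
                        "vary": [0.0, 0.5, 0.4]},     # SD 0.216 > 0.1
                       index=["p1", "p2", "p3"])
    retained, n_excl = nonmyeloid_signature(sig, sd_threshold=0.1)
    assert retained == ["flat"] and n_excl == 1


def test_nonmyeloid_signature_matches_brute_force():
    rng = np.random.default_rng(9)
    sig = pd.DataFrame(rng.random((4, 100)) * 0.4,
                       columns=[f"g{j}" for j in range(100)])
    retained, n_excl = nonmyeloid_signature(sig, sd_threshold=0.1)
    want = [g for g in sig.columns if np.std(sig[g].to_numpy()) <= 0.1]
    assert retained == want
    assert n_excl == 100 - len(want)
    with pytest.raises(ValueError):
        nonmyeloid_signature(pd.DataFrame())


def test_environment_markers_extreme_and_boundary(sim_spots):
    ds, truth = sim_spots
    qc = qc_normalize(ds)
    tr = truth["environment"].loc[qc.adata.obs_names].to_numpy()
    qc.set_environment(tr)
    retained = [g for g in qc.genes if not g.startswith("MYE-")]
    markers = environment_markers(qc, retained)
    for e, planted in truth["degs"].items():
        got = set(markers[e]["gene"])
        assert len(got & set(planted)) >= 0.8 * len(planted)


def test_environment_markers_null_type_one():
    rng = np.random.default_rng(10)
    counts = pd.DataFrame(rng.poisson(40, (250, 200)),
                          columns=[f"g{j}" for j in range(200)])
    ds = qc_normalize(_tiny_dataset(counts), min_counts=100)
    ds.set_environment(rng.integers(0, 5, ds.n_spots))
    markers = environment_markers(ds, list(ds.genes), p_max=0.01, min_fold=1.0)
    mean_len = np.mean([len(df) for df in markers.values()])
    assert mean_len <= 0.01 * 200 * 2


def test_environment_markers_fold_gate():
    # strongly significant but sub-threshold fold changes are rejected
    rng = np.random.default_rng(11)
    n = 200
    counts = pd.DataFrame({
        "steady": rng.poisson(500, n),
        "weak": np.r_[rng.poisson(575, n // 2), rng.poisson(500, n // 2)],  # ~1.15x
        "strong": np.r_[rng.poisson(2000, n // 2), rng.poisson(500, n // 2)],
    })
    ds = qc_normalize(_tiny_dataset(counts), min_counts=100)
    ds.set_environment(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)])
    markers = environment_markers(ds, ["steady", "weak", "strong"],
                                  p_max=0.01, min_fold=1.5)
    assert "strong" in set(markers[0]["gene"])
    assert "weak" not in set(markers[0]["gene"])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def test_survival_recovers_planted_beta():
    cohort, truth = simulate_cohort(400, [0.05, 0.0, 0.0], censor_frac=0.2, seed=21)
    table, km = survival_association(cohort)
    beta_hat = table.set_index("environment").loc["env_0", "log_hr"]
    assert beta_hat == pytest.approx(0.05, abs=0.015)


def test_survival_median_split_even_groups():
    cohort, _ = simulate_cohort(100, [0.05, 0.0], censor_frac=0.0, seed=22)
    _, km = survival_association(cohort)
    for env, info in km.items():
        n_high = info["high_mask"].sum()
        assert abs(n_high - 50) <= 1          # ties at the median only


def test_survival_constant_covariate_flagged():
    cohort, _ = simulate_cohort(50, [0.0, 0.0], censor_frac=0.0, seed=23)
    cohort.df["env_0"] = 0.5
    table, _ = survival_association(cohort)
    row = table.set_index("environment").loc["env_0"]
    assert not row["defined"] and "constant" in row["flag"]


def test_survival_cohort_validation():
    df = pd.DataFrame({"sample_id": ["a"], "time": [-1.0], "event": [1],
                       "env_0": [0.5]})
    with pytest.raises(ValueError, match="positive"):
        SurvivalCohort(df)
    cohort, _ = simulate_cohort(10, [0.0], censor_frac=0.0, seed=1)
    with pytest.raises(ValueError, match="too small"):
        survival_association(cohort)
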