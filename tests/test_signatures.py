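"""Gene-set statistics: truncated-z enrichment, markers with the
unique-marker rule, preranked GSEA, hypergeometric ORA, target activation."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

from reprotalk import signatures as sig


def make_ds(X, genes=None):
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = genes or [f"G{j}" for j in range(g)]
    ds = ad.AnnData(X=X.astype(np.float32),
                    obs=pd.DataFrame(index=pd.Index([f"C{i}" for i in range(n)])),
                    var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return ds


# ---------------------------------------------------------------------------
# enrichment score


def test_singleton_set_score_is_gene_z():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 3))
    ds = make_ds(X)
    es = sig.cell_enrichment_score(ds, ["G1"])
    z = (X[:, 1] - X[:, 1].mean()) / X[:, 1].std()
    assert np.allclose(es, np.clip(z, -5, 5), atol=1e-5)


def test_constant_genes_score_zero():
    ds = make_ds(np.ones((10, 4)))
    es = sig.cell_enrichment_score(ds, ["G0", "G2"])
    assert np.allclose(es, 0.0)


def test_toy_matrix_matches_manual_clipped_z():
    X = np.array([[0.0, 1.0, 5.0],
                  [1.0, 1.0, 0.0],
                  [2.0, 3.0, 0.0],
                  [3.0, 1.0, 0.0]])
    ds = make_ds(X)
    es = sig.cell_enrichment_score(ds, ["G0", "G1", "G2"],
                                   sig.EnrichmentParams(z_truncation=1.0))
    Z = (X - X.mean(0)) / X.std(0)
    expected = np.clip(Z, -1, 1).mean(axis=1)
    assert np.allclose(es, expected, atol=1e-5)


def test_absent_genes_dropped_and_all_absent_errors():
    ds = make_ds(np.random.default_rng(1).normal(size=(10, 3)))
    a = sig.cell_enrichment_score(ds, ["G0", "NOTTHERE"])
    b = sig.cell_enrichment_score(ds, ["G0"])
    assert np.allclose(a, b)
    with pytest.raises(ValueError):
        sig.cell_enrichment_score(ds, ["NOPE"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.5, 5.0))
def test_score_bounded_by_truncation(seed, trunc):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(20, 6)) * rng.uniform(0.1, 10, size=6)
    ds = make_ds(X)
    es = sig.cell_enrichment_score(ds, [f"G{j}" for j in range(6)],
                                   sig.EnrichmentParams(z_truncation=trunc))
    assert np.all(es >= -trunc - 1e-9) and np.all(es <= trunc + 1e-9)


# ---------------------------------------------------------------------------
# markers


def test_exclusive_gene_is_unique_marker():
    X = np.zeros((30, 2))
    clusters = np.repeat(["A", "B", "C"], 10)
    X[:10, 0] = 5.0                      # G0 exclusive to cluster A
    X[:, 1] = np.random.default_rng(0).normal(5, 0.1, 30)
    df = sig.find_markers(make_ds(X), clusters,
                          sig.MarkerParams(min_lfc=0.25, max_fdr=0.05))
    assert set(df["gene"]) == {"G0"}
    assert df.loc[df["gene"] == "G0", "cluster"].item() == "A"
    assert df["unique"].all()


def test_unique_marker_prefers_highest_lfc():
    """A gene passing in two clusters is retained only where LFC is
    highest."""
    X = np.zeros((30, 1))
    clusters = np.repeat(["A", "B", "C"], 10)
    X[:10, 0] = 8.0                      # strong in A
    X[10:20, 0] = 2.0                    # weaker but significant in B
    df = sig.find_markers(make_ds(X), clusters,
                          sig.MarkerParams(min_lfc=0.25, max_fdr=0.05))
    assert len(df) == 1 and df.loc[0, "cluster"] == "A"


def test_marker_pvalues_match_scipy_rank_sum(prep_small):
    """Vectorised rank-sum p-values equal scipy.stats.mannwhitneyu
    (asymptotic, tie-corrected, continuity-corrected) to 1e-10."""
    ds, truth = prep_small
    sub = ds[:90, :40].copy()
    clusters = np.repeat(["A", "B", "C"], 30)
    df = sig.find_markers(sub, clusters, sig.MarkerParams(min_lfc=0.0,
                                                          max_fdr=0.999999))
    X = sub.X.toarray().astype(np.float64)
    checked = 0
    for _, row in df.iterrows():
        j = sub.var_names.get_loc(row["gene"])
        mask = clusters == row["cluster"]
        ref = stats.mannwhitneyu(X[mask, j], X[~mask, j],
                                 alternative="two-sided",
                                 method="asymptotic").pvalue
        assert abs(row["p"] - ref) < 1e-10
        checked += 1
    assert checked > 10


def test_unique_markers_have_no_duplicates(prep_small):
    ds, truth = prep_small
    clusters = truth.cell_trajectory.reindex(ds.obs_names).to_numpy()
    df = sig.find_markers(ds, clusters, sig.MarkerParams())
    assert df["gene"].is_unique


# ---------------------------------------------------------------------------
# preranked GSEA


def manual_running_es(scores, members):
    """Independent hand-traceable running sum (weight = |score|)."""
    hit_w = np.abs(scores) * members
    p_hit = np.cumsum(hit_w) / hit_w.sum()
    p_miss = np.cumsum(1.0 - members) / (len(members) - members.sum())
    running = p_hit - p_miss
    return running[np.argmax(np.abs(running))]


def test_gsea_top_ranked_set_maximal():
    ranked = pd.Series(np.linspace(3, -3, 50),
                       index=[f"G{j}" for j in range(50)])
    out = sig.preranked_gsea(ranked, {"top": [f"G{j}" for j in range(5)]},
                             n_perm=200, seed=0)
    assert out.loc[0, "es"] > 0.9
    assert out.loc[0, "p"] == pytest.approx(1 / 201)


def test_gsea_hand_traced_small_ranking():
    scores = np.array([5.0, 4, 3, 2, 1, 0.5, -0.5, -1, -2, -3])
    ranked = pd.Series(scores, index=[f"G{j}" for j in range(10)])
    members = np.zeros(10)
    members[[0, 3, 7]] = 1
    expected = manual_running_es(scores, members)
    out = sig.preranked_gsea(ranked, {"s": ["G0", "G3", "G7"]},
                             n_perm=100, seed=0)
    assert out.loc[0, "es"] == pytest.approx(expected)


def test_gsea_random_sets_centered():
    rng = np.random.default_rng(4)
    ranked = pd.Series(rng.normal(size=200),
                       index=[f"G{j}" for j in range(200)])
    sets = {f"s{k}": list(rng.choice(ranked.index, 15, replace=False))
            for k in range(60)}
    out = sig.preranked_gsea(ranked, sets, n_perm=100, seed=1)
    assert abs(out["nes"].mean()) < 0.3
    assert out["p"].min() > 0.001


# ---------------------------------------------------------------------------
# ORA


def test_ora_closed_forms():
    universe = [f"G{j}" for j in range(10)]
    s = universe[:5]
    assert sig.ora_hypergeometric(universe, universe, universe) == 1.0
    assert sig.ora_hypergeometric(s, s, universe) == pytest.approx(1 / 252)


def test_ora_matches_brute_force_enumeration():
    """Exact agreement with enumeration of all draws on universes <= 20."""
    from math import comb
    rng = np.random.default_rng(7)
    for _ in range(20):
        N = int(rng.integers(5, 21))
        universe = [f"G{j}" for j in range(N)]
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        gene_set = list(rng.choice(universe, K, replace=False))
        hits = list(rng.choice(universe, n, replace=False))
        k_obs = len(set(hits) & set(gene_set))
        exact = sum(comb(K, k) * comb(N - K, n - k)
                    for k in range(k_obs, min(K, n) + 1)) / comb(N, n)
        assert sig.ora_hypergeometric(hits, gene_set, universe) == \
            pytest.approx(exact, rel=1e-12)


# ---------------------------------------------------------------------------
# target activation


def test_activation_p_floor_for_maximal_cell():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 30))
    targets = [f"G{j}" for j in range(5)]
    X[0, :5] = 30.0                          # all-max targets for cell 0
    out = sig.target_activation(make_ds(X), targets,
                                sig.EnrichmentParams(n_null=200, seed=0))
    assert out["p"].iloc[0] == pytest.approx(1 / 201)
    assert out["active"].iloc[0]


def test_activation_type_I_calibrated():
    """With a random target set the active fraction stays near the nominal
    5% level."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(400, 100))
    targets = [f"G{j}" for j in rng.choice(100, 10, replace=False)]
    out = sig.target_activation(make_ds(X), targets,
                                sig.EnrichmentParams(n_null=500, seed=1))
    assert out["active"].mean() < 0.10


def test_planted_pathway_activation(prep_small, gene_sets):
    """>=80% of developmental cells after day 5 are flagged active for the
    planted pathway target set."""
    ds, truth = prep_small
    out = sig.target_activation(ds, truth.gene_signatures["STAT3_targets"],
                                sig.EnrichmentParams(seed=2))
    traj = truth.cell_trajectory.reindex(ds.obs_names)
    mask = ((traj == "developmental") & (ds.obs["day"] > 5)).to_numpy()
    assert out["active"].to_numpy()[mask].mean() >= 0.80
    assert out["active"].to_numpy()[~mask].mean() < 0.10


def test_empirical_p_uniform_under_null():
    """Across cells of a null dataset, the empirical p-values are uniform
    (KS D < 0.1 at 500 draws)."""
    rng = np.random.default_rng(9)
    X = rng.normal(size=(500, 120))
    targets = [f"G{j}" for j in range(8)]
    out = sig.target_activation(make_ds(X), targets,
                                sig.EnrichmentParams(n_null=1000, seed=4))
    d = stats.kstest(out["p"], "uniform").statistic
    assert d < 0.1
    assert out["p"].min() >= 1 / 1001 and out["p"].max() <= 1.0
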