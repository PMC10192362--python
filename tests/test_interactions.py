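"""Ligand-receptor pair cascade, sIS permutation scoring, top-pair rule,
cluster-pair scores and the fuzzy-AND score — checked against exhaustive or
independent brute-force oracles on tiny instances."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from reprotalk import interactions as ia


def make_ds(X, genes=None, days=None):
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = genes or [f"G{j}" for j in range(g)]
    obs = pd.DataFrame({"day": days if days is not None else 0},
                       index=pd.Index([f"C{i}" for i in range(n)]))
    return ad.AnnData(X=X.astype(np.float32), obs=obs,
                      var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def pair_df(pairs):
    return pd.DataFrame(pairs, columns=["ligand", "receptor"])


# ---------------------------------------------------------------------------
# pair universe


def test_cascade_all_pass():
    genes = ["L1", "L2", "L3", "R1", "R2", "R3", "R4"]
    X = np.ones((3, 7))
    ds = make_ds(X, genes)
    validated = pair_df([(l, r) for l in genes[:3] for r in genes[3:]])
    pairs, cascade = ia.build_pair_universe(
        genes[:3], genes[3:], ds, validated, candidate_receptors=genes[3:])
    assert list(cascade.values()) == [12, 12, 12, 12]


def test_cascade_counts_match_set_algebra():
    genes = ["L1", "L2", "R1", "R2", "R3"]
    X = np.ones((4, 5))
    X[:, genes.index("R3")] = 0           # R3 never expressed
    ds = make_ds(X, genes)
    annotated = ["R1", "R3"]              # R2 unannotated
    validated = pair_df([("L1", "R1"), ("L2", "R3")])
    pairs, cascade = ia.build_pair_universe(
        ["L1", "L2"], annotated, ds, validated,
        candidate_receptors=["R1", "R2", "R3"])
    # oracle: 2x3 = 6; annotation keeps {R1, R3} -> 4; expression drops R3
    # pairs -> 2; validated keeps L1-R1 only
    assert list(cascade.values()) == [6, 4, 2, 1]
    assert pairs.iloc[0][["ligand", "receptor"]].tolist() == ["L1", "R1"]
    counts = list(cascade.values())
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_empty_ligand_list_errors(prep_small):
    ds, _ = prep_small
    with pytest.raises(ValueError, match="ligand"):
        ia.build_pair_universe([], ["R"], ds, pair_df([]))


# ---------------------------------------------------------------------------
# sIS


def test_sis_constant_genes_null():
    X = np.ones((20, 2))
    ds = make_ds(X, ["L", "R"])
    member = pd.Series([True] * 8 + [False] * 12, index=ds.obs_names)
    other = pd.Series([False] * 12 + [True] * 8, index=ds.obs_names)
    rec = ia.sis_timecourse(ds, member, other, pair_df([("L", "R")]),
                            ia.InteractionParams(n_perm=200, seed=0))
    assert rec.loc[0, "sis"] == 0.0
    assert rec.loc[0, "p"] == 1.0


def test_sis_matches_exhaustive_enumeration():
    """6 cells, 2 genes: the sampled permutation null converges to the exact
    null enumerated over all source/target member-set choices."""
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 3, size=(6, 2))
    ds = make_ds(X, ["L", "R"])
    src = pd.Series([True, True, False, False, False, False],
                    index=ds.obs_names)
    tgt = pd.Series([False, False, False, False, True, True],
                    index=ds.obs_names)
    rec = ia.sis_timecourse(ds, src, tgt, pair_df([("L", "R")]),
                            ia.InteractionParams(n_perm=4000, seed=1))
    raw = X[:2, 0].mean() * X[4:, 1].mean()
    null = [X[list(s), 0].mean() * X[list(t), 1].mean()
            for s in itertools.combinations(range(6), 2)
            for t in itertools.combinations(range(6), 2)]
    null = np.array(null)
    sis_exact = (raw - null.mean()) / null.std()
    p_exact = (null >= raw).mean()
    assert rec.loc[0, "raw"] == pytest.approx(raw, rel=1e-6)
    assert rec.loc[0, "sis"] == pytest.approx(sis_exact, abs=0.15)
    assert rec.loc[0, "p"] == pytest.approx(p_exact, abs=0.05)


def test_sis_detects_planted_pair_only_in_window(sim_small):
    """The planted ligand-receptor pair is significant inside its planted
    day window and not before the branch."""
    from reprotalk import preprocess as pp
    config, adata, truth = sim_small
    p = pp.QCParams(min_genes=100, seed=0)
    ds = pp.normalize_and_filter_genes(
        pp.downsample_per_timepoint(pp.qc_filter(adata.copy(), p), p), p)
    traj = truth.cell_trajectory.reindex(ds.obs_names)
    rec = ia.sis_timecourse(ds, traj == "secretory", traj == "developmental",
                            pair_df([("LIG1", "REC1")]),
                            ia.InteractionParams(n_perm=500, seed=3))
    # pre-branch days have empty populations and are skipped
    assert set(rec["day"]) == {9, 11, 13, 15}
    in_window = rec[rec["day"] >= 9]
    assert (in_window["p"] < 0.05).all()
    assert (in_window["sis"] > 2).all()


def test_sis_reproducible(sim_small):
    from reprotalk import preprocess as pp
    _, adata, truth = sim_small
    p = pp.QCParams(min_genes=100, seed=0)
    ds = pp.normalize_and_filter_genes(
        pp.downsample_per_timepoint(pp.qc_filter(adata.copy(), p), p), p)
    traj = truth.cell_trajectory.reindex(ds.obs_names)
    params = ia.InteractionParams(n_perm=150, seed=9)
    a = ia.sis_timecourse(ds, traj == "secretory", traj == "developmental",
                          pair_df([("LIG1", "REC1")]), params)
    b = ia.sis_timecourse(ds, traj == "secretory", traj == "developmental",
                          pair_df([("LIG1", "REC1")]), params)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# top-pair rule


def test_single_day_returns_its_top_pair():
    rec = pd.DataFrame({"ligand": list("abc"), "receptor": list("xyz"),
                        "day": 1, "sis": [3.0, 1.0, 2.0]})
    top = ia.select_top_pairs(rec)
    assert len(top) == 1 and top.loc[0, "ligand"] == "a"


def test_three_day_table_hand_traced():
    """Six pairs over three days: the selection window spans from the global
    best record (always a day-top) to the last day-top in sIS order."""
    rows = [
        ("p1", 1, 5.0), ("p2", 1, 4.0),
        ("p3", 2, 4.5), ("p4", 2, 1.0),
        ("p5", 3, 2.0), ("p6", 3, 1.5),
        ("p2", 2, 0.5), ("p1", 3, 0.2),
    ]
    rec = pd.DataFrame([{"ligand": n, "receptor": "r", "day": d, "sis": s}
                        for n, d, s in rows])
    top = ia.select_top_pairs(rec)
    # global order: p1(5.0) p3(4.5) p2(4.0) p5(2.0) p6(1.5) p4(1.0) ...
    # day tops: p1 (day1, pos 0), p3 (day2, pos 1), p5 (day3, pos 3)
    # window positions 0..3 -> pairs p1, p3, p2, p5
    assert top["ligand"].tolist() == ["p1", "p3", "p2", "p5"]
    min_day_top = 2.0
    assert (top["sis"] >= min_day_top).all()


def test_selected_pairs_bounded_by_day_top(sim_small):
    rng = np.random.default_rng(1)
    rec = pd.DataFrame({
        "ligand": rng.choice(list("abcdefgh"), 60),
        "receptor": "r", "day": rng.integers(0, 4, 60),
        "sis": rng.normal(size=60)})
    rec = rec.drop_duplicates(["ligand", "receptor", "day"])
    top = ia.select_top_pairs(rec)
    min_day_top = rec.groupby("day")["sis"].max().min()
    assert (top["sis"] >= min_day_top - 1e-12).all()


# ---------------------------------------------------------------------------
# cluster pair score


def test_cluster_scores_identical_cells():
    X = np.ones((12, 2))
    ds = make_ds(X, ["L", "R"])
    clusters = np.repeat([0, 1, 2], 4)
    score, pmat = ia.cluster_pair_score(ds, clusters, "L", "R",
                                        ia.InteractionParams(n_perm=100, seed=0))
    assert np.allclose(score.to_numpy(), 1.0)
    assert (pmat.to_numpy() >= 0.99).all()


def test_cluster_scores_exclusive_expression():
    X = np.zeros((12, 2))
    clusters = np.repeat(["A", "B", "C"], 4)
    X[:4, 0] = 2.0                       # ligand only in A
    X[4:8, 1] = 3.0                      # receptor only in B
    ds = make_ds(X, ["L", "R"])
    score, pmat = ia.cluster_pair_score(ds, clusters, "L", "R",
                                        ia.InteractionParams(n_perm=400, seed=0))
    assert score.loc["A", "B"] == score.to_numpy().max()
    assert pmat.loc["A", "B"] == pmat.to_numpy().min()


def test_cluster_score_p_matches_enumeration():
    """12 cells in 3 clusters: sampled label-permutation p converges to the
    exact p enumerated over all distinct label assignments."""
    from sympy.utilities.iterables import multiset_permutations
    rng = np.random.default_rng(4)
    X = rng.uniform(0, 2, size=(12, 2))
    ds = make_ds(X, ["L", "R"])
    clusters = np.repeat([0, 1, 2], 4)
    score, pmat = ia.cluster_pair_score(ds, clusters, "L", "R",
                                        ia.InteractionParams(n_perm=3000, seed=2))
    lig, rec = X[:, 0], X[:, 1]
    obs = score.to_numpy()
    exceed = np.zeros((3, 3))
    total = 0
    for perm in multiset_permutations([0] * 4 + [1] * 4 + [2] * 4):
        lab = np.array(perm)
        lm = np.array([lig[lab == k].mean() for k in range(3)])
        rm = np.array([rec[lab == k].mean() for k in range(3)])
        exceed += np.outer(lm, rm) >= obs
        total += 1
    exact = exceed / total
    assert np.abs(pmat.to_numpy() - exact).max() < 0.04


# ---------------------------------------------------------------------------
# fuzzy AND


def test_fuzzy_top_gene_at_ceiling(rng):
    X = rng.uniform(0, 1, size=(10, 40))
    X[:, 0] = 5.0                        # ligand strictly above everything
    X[:, 1] = np.median(X[:, 2:])        # receptor near the median
    ds = make_ds(X)
    out = ia.fuzzy_and_score(ds, np.ones(10, bool), ("G0", "G1"),
                             ia.InteractionParams(n_perm=100, seed=0,
                                                  n_null_genes=30))
    assert out["ligand_score"] >= 0.95
    assert 0.2 < out["receptor_score"] < 0.8
    assert out["score"] == min(out["ligand_score"], out["receptor_score"])


def test_fuzzy_p_matches_brute_force():
    """5 cells x 8 genes: empirical p agrees with an independent loop-based
    recomputation of the permutation null."""
    rng = np.random.default_rng(6)
    X = rng.uniform(0, 1, size=(5, 8))
    X[:, 0] += 1.0
    ds = make_ds(X)
    params = ia.InteractionParams(n_perm=3000, seed=3, n_null_genes=8)
    out = ia.fuzzy_and_score(ds, np.ones(5, bool), ("G0", "G3"), params)

    # oracle: plain loops, separate RNG
    orng = np.random.default_rng(99)
    null_ix = np.arange(8)

    def pair_score(M):
        means = M.mean(axis=0)
        ls = np.mean(means[null_ix] < means[0])
        rs = np.mean(means[null_ix] < means[3])
        return min(ls, rs)

    obs = pair_score(X)
    exceed = 0
    n_oracle = 4000
    for _ in range(n_oracle):
        Xp = np.array([row[orng.permutation(8)] for row in X])
        exceed += pair_score(Xp) >= obs
    p_oracle = (1 + exceed) / (n_oracle + 1)
    # n_null_genes = all 8 genes, so both routes use the same null set
    assert out["score"] == pytest.approx(obs, abs=1e-9)
    assert out["p"] == pytest.approx(p_oracle, abs=0.05)


def test_fuzzy_pair_score_never_exceeds_components(rng):
    for _ in range(5):
        X = rng.uniform(0, 2, size=(8, 20))
        ds = make_ds(X)
        out = ia.fuzzy_and_score(ds, np.ones(8, bool), ("G2", "G5"),
                                 ia.InteractionParams(n_perm=100, seed=1,
                                                      n_null_genes=15))
        assert out["score"] <= out["ligand_score"] + 1e-12
        assert out["score"] <= out["receptor_score"] + 1e-12


def test_fuzzy_empty_cell_set_errors(rng):
    ds = make_ds(rng.uniform(size=(5, 6)))
    with pytest.raises(ValueError, match="empty"):
        ia.fuzzy_and_score(ds, np.zeros(5, bool), ("G0", "G1"),
                           ia.InteractionParams(n_perm=100, seed=0))
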