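"""Ligand-receptor interaction analysis.

Pair universe: secreted ligands crossed with every candidate receptor, then a
three-stage filter cascade (receptor annotation, expression of both genes in
at least one cell, experimentally validated pairs).  Scores:

* ``sis_timecourse`` — per pair per day, the product of the mean ligand
  expression over the source-trajectory members and the mean receptor
  expression over the target-trajectory members, z-standardised against a
  null that permutes the membership labels among the day's cells (sIS);
* ``select_top_pairs`` — the published top-pair rule: order all records by
  sIS, mark each day's best pair, and keep every unique pair whose best
  record falls between the first and last day-top occurrence in that order;
* ``cluster_pair_score`` — mean ligand in cluster A times mean receptor in
  cluster B for every ordered cluster pair, with a cell-to-cluster
  permutation null;
* ``fuzzy_and_score`` — ligand and receptor each scored as the fraction of
  random genes whose mean expression in the cell set lies below the gene's
  own mean; the pair score is the minimum of the two (fuzzy AND), with a
  null that permutes each cell's expression vector independently.  A
  fold-change variant scores log2 expression relative to each gene's average
  over the whole matrix.

All empirical p-values use the add-one estimator (1 + #null >= obs) /
(n_perm + 1), one-sided (greater).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

import anndata as ad

log = logging.getLogger(__name__)

__all__ = [
    "InteractionParams", "build_pair_universe", "sis_timecourse",
    "select_top_pairs", "cluster_pair_score", "fuzzy_and_score",
]


@dataclass
class InteractionParams:
    n_perm: int = 1000
    seed: int = 0
    n_null_genes: int = 200
    fc_variant: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def build_pair_universe(ligands: list[str], receptor_annotation: list[str],
                        ds: ad.AnnData, validated: pd.DataFrame,
                        candidate_receptors: list[str] | None = None,
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cross ligands with candidate receptors and apply the filter cascade.

    ``candidate_receptors`` defaults to every gene in the dataset ("every
    possible receptor").  Cascade: (1) keep receptor-annotated partners,
    (2) keep pairs with both genes expressed in at least one cell, (3) keep
    experimentally validated pairs.  Returns the pair table with per-stage
    flags and the cascade counts in order.
    """
    if not ligands:
        raise ValueError("empty ligand list")
    if candidate_receptors is None:
        candidate_receptors = list(ds.var_names)
    annot = set(receptor_annotation)
    valid_set = set(zip(validated["ligand"], validated["receptor"]))
    X = _dense(ds.X)
    expressed = {g for g, nz in zip(ds.var_names, (X > 0).any(axis=0)) if nz}

    rows = []
    for lig in ligands:
        for rec in candidate_receptors:
            rows.append({
                "ligand": lig, "receptor": rec,
                "receptor_annotated": rec in annot,
                "expressed_somewhere": lig in expressed and rec in expressed,
                "validated": (lig, rec) in valid_set,
            })
    df = pd.DataFrame(rows).drop_duplicates(["ligand", "receptor"])
    cascade = {"initial": len(df)}
    df = df[df["receptor_annotated"]]
    cascade["receptor_annotated"] = len(df)
    df = df[df["expressed_somewhere"]]
    cascade["expressed"] = len(df)
    df = df[df["validated"]]
    cascade["validated"] = len(df)
    return df.reset_index(drop=True), cascade


def sis_timecourse(ds: ad.AnnData, source_membership: pd.Series,
                   target_membership: pd.Series, pairs: pd.DataFrame,
                   p: InteractionParams | None = None) -> pd.DataFrame:
    """Standardised interaction score per pair per day.

    raw = mean ligand expression over source members x mean receptor
    expression over target members (normalised values).  The null permutes
    the source and target member labels independently among the day's cells;
    sIS = (raw - null mean) / null sd; empirical p one-sided greater.
    Days where either population is empty are skipped with a warning.
    """
    p = p or InteractionParams()
    rng = np.random.default_rng(p.seed)
    genes = sorted(set(pairs["ligand"]) | set(pairs["receptor"]))
    genes = [g for g in genes if g in ds.var_names]
    gix = {g: i for i, g in enumerate(genes)}
    Xg = _dense(ds[:, genes].X).astype(float)
    src = source_membership.reindex(ds.obs_names).fillna(False).to_numpy(dtype=bool)
    tgt = target_membership.reindex(ds.obs_names).fillna(False).to_numpy(dtype=bool)
    day_arr = ds.obs["day"].to_numpy()

    records = []
    for day in sorted(pd.unique(day_arr)):
        ix = np.where(day_arr == day)[0]
        ns = int(src[ix].sum())
        nt = int(tgt[ix].sum())
        if ns == 0 or nt == 0:
            log.warning("day %s: empty source or target population; skipped", day)
            continue
        Xd = Xg[ix]
        n = ix.size
        lig_obs = Xd[src[ix]].mean(axis=0)
        rec_obs = Xd[tgt[ix]].mean(axis=0)
        # shared permutation null across pairs at this day
        lig_null = np.empty((p.n_perm, len(genes)))
        rec_null = np.empty((p.n_perm, len(genes)))
        for b in range(p.n_perm):
            s_sel = rng.choice(n, size=ns, replace=False)
            t_sel = rng.choice(n, size=nt, replace=False)
            lig_null[b] = Xd[s_sel].mean(axis=0)
            rec_null[b] = Xd[t_sel].mean(axis=0)
        for _, row in pairs.iterrows():
            li = gix.get(row["ligand"])
            ri = gix.get(row["receptor"])
            if li is None or ri is None:
                continue
            raw = lig_obs[li] * rec_obs[ri]
            null = lig_null[:, li] * rec_null[:, ri]
            sd = null.std()
            sis = (raw - null.mean()) / sd if sd > 0 else 0.0
            pv = (1 + np.sum(null >= raw)) / (p.n_perm + 1)
            records.append({
                "ligand": row["ligand"], "receptor": row["receptor"],
                "day": day, "raw": raw, "sis": float(sis), "p": float(pv),
                "n_perm": p.n_perm, "seed": p.seed,
            })
    return pd.DataFrame(records)


def select_top_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Top-pair selection rule over the sIS table.

    All records are ordered by descending sIS; the best record of each day is
    marked; every unique pair whose best record sits between the first and
    the last day-top occurrence (inclusive) in that global ordering is
    returned, ordered by its best sIS.
    """
    if records.empty:
        return records.copy()
    df = records.sort_values("sis", ascending=False).reset_index(drop=True)
    day_top_pos = df.groupby("day")["sis"].idxmax()
    lo, hi = int(day_top_pos.min()), int(day_top_pos.max())
    best = df.drop_duplicates(["ligand", "receptor"])  # best record per pair
    sel = best[(best.index >= lo) & (best.index <= hi)]
    return sel.reset_index(drop=True)


def cluster_pair_score(ds: ad.AnnData, clusters: np.ndarray, ligand: str,
                       receptor: str, p: InteractionParams | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-to-cluster interaction score for one pair.

    score[A, B] = mean ligand expression in cluster A x mean receptor
    expression in cluster B for every ordered cluster pair; the null permutes
    the cell-to-cluster association ``n_perm`` times.  Returns (score matrix,
    empirical p matrix) as DataFrames indexed by source/target cluster.
    Singleton clusters are allowed (logged).
    """
    p = p or InteractionParams()
    rng = np.random.default_rng(p.seed)
    labels = np.asarray(clusters)
    uniq = pd.unique(labels)
    code = pd.Series(labels).map({c: i for i, c in enumerate(uniq)}).to_numpy()
    K = len(uniq)
    for c in uniq:
        if (labels == c).sum() == 1:
            log.info("cluster %s is a singleton", c)
    lig = _dense(ds[:, [ligand]].X).ravel().astype(float)
    rec = _dense(ds[:, [receptor]].X).ravel().astype(float)
    counts = np.bincount(code, minlength=K).astype(float)

    def cluster_means(perm_code: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lm = np.bincount(perm_code, weights=lig, minlength=K) / counts
        rm = np.bincount(perm_code, weights=rec, minlength=K) / counts
        return lm, rm

    lm, rm = cluster_means(code)
    score = np.outer(lm, rm)
    exceed = np.zeros_like(score)
    for _ in range(p.n_perm):
        perm = rng.permutation(code)
        plm, prm = cluster_means(perm)
        exceed += np.outer(plm, prm) >= score
    pmat = (1 + exceed) / (p.n_perm + 1)
    idx = pd.Index(uniq, name="source_cluster")
    cols = pd.Index(uniq, name="target_cluster")
    return (pd.DataFrame(score, index=idx, columns=cols),
            pd.DataFrame(pmat, index=idx, columns=cols))


def _fuzzy_scores(X: np.ndarray, li: int, ri: int, null_ix: np.ndarray,
                  ) -> tuple[float, float, float]:
    """(ligand score, receptor score, pair score) for a cell-set matrix."""
    means = X.mean(axis=0)
    lig_score = float(np.mean(means[null_ix] < means[li]))
    rec_score = float(np.mean(means[null_ix] < means[ri]))
    return lig_score, rec_score, min(lig_score, rec_score)


def fuzzy_and_score(ds: ad.AnnData, cell_mask: np.ndarray | pd.Series,
                    pair: tuple[str, str],
                    p: InteractionParams | None = None) -> dict[str, float]:
    """Fuzzy-AND interaction score for one pair in one trajectory/time cell
    set, with an empirical p from per-cell expression permutations.

    Ligand (receptor) score: fraction of ``n_null_genes`` random genes whose
    mean expression over the cell set is below the ligand's (receptor's);
    pair score = min of the two.  The null permutes every cell's expression
    vector independently and recomputes the pair score.  When
    ``p.fc_variant``, the same computation runs on log2 expression relative
    to each gene's average over the entire matrix.
    """
    p = p or InteractionParams()
    rng = np.random.default_rng(p.seed)
    if isinstance(cell_mask, pd.Series):
        cell_mask = cell_mask.reindex(ds.obs_names).fillna(False).to_numpy(dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() == 0:
        raise ValueError("empty cell set")
    ligand, receptor = pair
    li = ds.var_names.get_loc(ligand)
    ri = ds.var_names.get_loc(receptor)
    X = _dense(ds.X).astype(float)
    if p.fc_variant:
        X = X - X.mean(axis=0, keepdims=True)
    Xs = X[cell_mask]
    n_null = min(p.n_null_genes, ds.n_vars)
    null_ix = rng.choice(ds.n_vars, size=n_null, replace=False)
    lig_s, rec_s, pair_s = _fuzzy_scores(Xs, li, ri, null_ix)
    exceed = 0
    for _ in range(p.n_perm):
        Xp = rng.permuted(Xs, axis=1)
        _, _, ps = _fuzzy_scores(Xp, li, ri, null_ix)
        exceed += ps >= pair_s
    pv = (1 + exceed) / (p.n_perm + 1)
    return {"ligand_score": lig_s, "receptor_score": rec_s,
            "score": pair_s, "p": float(pv)}
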