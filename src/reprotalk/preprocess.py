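"""Single-cell QC, per-time-point downsampling, gene filtering and
normalisation.

The stage order is fixed and idempotent: QC filter (detected genes,
mitochondrial fraction) -> random downsampling to a per-day cap -> gene
prevalence filter computed on all retained cells -> counts-per-million,
log2(x + 1).  Cell-cycle phases are assigned from module scores of S and G2M
gene sets (mean expression of the set minus an expression-matched control
set), phase = argmax of the positive scores, else G1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

import anndata as ad
import scanpy as sc

from .datasets import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = ["QCParams", "qc_filter", "downsample_per_timepoint",
           "normalize_and_filter_genes", "score_cell_cycle"]


@dataclass
class QCParams:
    min_genes: int = 1000
    max_mito: float = 0.10
    cap_per_day: int = 2500
    min_prevalence: float = 0.05
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_genes, self.cap_per_day) <= 0 or self.pseudocount <= 0:
            raise ValueError("QC parameters must be positive")
        if not 0 < self.max_mito <= 1:
            raise ValueError("max_mito must be in (0, 1]")
        if not 0 < self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in (0, 1]")


def _counts(ds: ad.AnnData) -> sparse.csr_matrix:
    X = ds.layers.get("counts", ds.X)
    return sparse.csr_matrix(X)


def qc_filter(ds: ad.AnnData, p: QCParams | None = None) -> ad.AnnData:
    """Remove cells with fewer than ``min_genes`` detected genes or a
    mitochondrial count fraction above ``max_mito``.

    Boundary semantics: exactly ``min_genes`` detected and exactly
    ``max_mito`` mitochondrial fraction are both retained.  Per-day removal
    counts are logged and stored in ``uns["qc_removed_per_day"]``.
    """
    p = p or QCParams()
    counts = _counts(ds)
    n_detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    total = np.asarray(counts.sum(axis=1)).ravel()
    if "mito" in ds.var and ds.var["mito"].any():
        mito_counts = np.asarray(
            counts[:, ds.var["mito"].to_numpy(dtype=bool)].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 1.0)
        mito_bad = mito_frac > p.max_mito
    else:
        log.warning("no mitochondrial gene flags; mito filter skipped")
        mito_frac = np.zeros(ds.n_obs)
        mito_bad = np.zeros(ds.n_obs, dtype=bool)
    bad = (n_detected < p.min_genes) | mito_bad
    out = ds[~bad].copy()
    out.obs["n_genes_detected"] = n_detected[~bad]
    out.obs["mito_fraction"] = mito_frac[~bad]
    if "day" in ds.obs:
        removed = ds.obs.loc[bad, "day"].value_counts().sort_index()
        out.uns["qc_removed_per_day"] = {str(k): int(v)
                                         for k, v in removed.items()}
        for day, n in removed.items():
            log.info("QC: removed %d cells at day %s", n, day)
    return out


def downsample_per_timepoint(ds: ad.AnnData, p: QCParams | None = None) -> ad.AnnData:
    """Uniformly subsample each day with more than ``cap_per_day`` cells down
    to exactly the cap; smaller days are kept whole.  Draws are made in
    ascending day order from a single generator seeded with ``p.seed``, so a
    fixed seed reproduces the barcode set."""
    p = p or QCParams()
    rng = np.random.default_rng(p.seed)
    keep_idx: list[np.ndarray] = []
    days = np.sort(ds.obs["day"].unique())
    for day in days:
        ix = np.where((ds.obs["day"] == day).to_numpy())[0]
        if ix.size > p.cap_per_day:
            ix = np.sort(rng.choice(ix, size=p.cap_per_day, replace=False))
        keep_idx.append(ix)
    keep = np.concatenate(keep_idx)
    return ds[np.sort(keep)].copy()


def normalize_and_filter_genes(ds: ad.AnnData, p: QCParams | None = None) -> ad.AnnData:
    """Drop genes detected in fewer than ``min_prevalence`` of all retained
    cells, then normalise each cell of the remaining matrix to counts per
    million and transform to log2(CPM + pseudocount)."""
    p = p or QCParams()
    counts = _counts(ds)
    prevalence = np.asarray((counts > 0).mean(axis=0)).ravel()
    keep = prevalence >= p.min_prevalence
    out = ds[:, keep].copy()
    out.var["prevalence"] = prevalence[keep]
    counts = _counts(out)
    row_sums = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(row_sums == 0):
        raise ValueError("cell with zero total count after gene filtering; "
                         "QC should have removed it")
    cpm = counts.multiply(1e6 / row_sums[:, None]).tocsr()
    norm = cpm.copy()
    norm.data = np.log2(norm.data + p.pseudocount)
    if p.pseudocount != 1.0:
        # log2 of the pseudocount alone is nonzero; densify correction
        norm = sparse.csr_matrix(
            np.log2(cpm.toarray() + p.pseudocount))
    out.layers["counts"] = counts
    out.X = norm.astype(np.float32)
    return out


def score_cell_cycle(ds: ad.AnnData, phase_sets: GeneSetCollection,
                     s_set: str = "SPhase", g2m_set: str = "G2MPhase",
                     seed: int = 0) -> ad.AnnData:
    """Assign S / G2M / G1 phases from module scores.

    Each phase score is the mean normalised expression of the phase set minus
    the mean of an expression-matched control set (25 expression bins, 50
    control genes per bin, seeded).  Phase is the argmax of the positive
    scores; if neither score is positive the cell is called G1.
    """
    for name in (s_set, g2m_set):
        if name not in phase_sets or not phase_sets[name]:
            raise ValueError(f"phase gene set {name!r} empty or missing")
    present = set(ds.var_names)
    s_genes = [g for g in phase_sets[s_set] if g in present]
    g2m_genes = [g for g in phase_sets[g2m_set] if g in present]
    dropped = (len(phase_sets[s_set]) - len(s_genes)
               + len(phase_sets[g2m_set]) - len(g2m_genes))
    if dropped:
        log.info("score_cell_cycle: %d phase genes absent from dataset", dropped)
    if not s_genes or not g2m_genes:
        raise ValueError("no phase genes present in the dataset")
    sc.tl.score_genes(ds, s_genes, score_name="S_score", ctrl_size=50,
                      n_bins=25, random_state=seed)
    sc.tl.score_genes(ds, g2m_genes, score_name="G2M_score", ctrl_size=50,
                      n_bins=25, random_state=seed)
    s = ds.obs["S_score"].to_numpy()
    g2m = ds.obs["G2M_score"].to_numpy()
    phase = np.where((s <= 0) & (g2m <= 0), "G1",
                     np.where(s >= g2m, "S", "G2M"))
    ds.obs["phase"] = pd.Categorical(phase, categories=["G1", "S", "G2M"])
    return ds
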