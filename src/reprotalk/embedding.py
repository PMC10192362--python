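"""Embedding, neighbour graph, force layout, Louvain clustering and
SR/DR/NA cluster annotation.

The cell embedding concatenates the first ``n_pcs`` principal components of
the normalised matrix with the first ``n_dms`` nontrivial diffusion-map
components computed from a Gaussian kernel on PCA space (adaptive bandwidth:
distance to the 15th neighbour; symmetric normalisation).  Both parts are
variance-standardised before concatenation.  A symmetric k-nearest-neighbour
graph on the joint embedding feeds a ForceAtlas2-style 2-D layout and Louvain
community detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import eigsh
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

import igraph

import anndata as ad

log = logging.getLogger(__name__)

__all__ = ["EmbedParams", "embed_cells", "force_layout", "cluster_cells",
           "annotate_clusters"]


@dataclass
class EmbedParams:
    n_pcs: int = 100
    n_dms: int = 20
    k_neighbors: int = 50
    fle_iterations: int = 1000
    resolution: float = 0.6
    seed: int = 0
    bandwidth_neighbor: int = 15

    def __post_init__(self) -> None:
        for v in (self.n_pcs, self.n_dms, self.k_neighbors,
                  self.fle_iterations):
            if v <= 0:
                raise ValueError("embedding parameters must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


def _diffusion_components(pcs: np.ndarray, n_dms: int, k_bw: int) -> np.ndarray:
    """Diffusion-map components from a Gaussian kernel on PCA space.

    Bandwidth per cell = distance to its ``k_bw``-th neighbour; the kernel is
    symmetrised, row/column degree-normalised (symmetric normalisation) and
    its top nontrivial eigenvectors are returned scaled by their eigenvalues.
    """
    n = pcs.shape[0]
    k_bw = min(k_bw, n - 1)
    nn = NearestNeighbors(n_neighbors=min(4 * k_bw, n - 1)).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    sigma = np.maximum(dist[:, k_bw - 1] if k_bw >= 1 else dist[:, -1], 1e-12)
    rows = np.repeat(np.arange(n), idx.shape[1])
    cols = idx.ravel()
    d = dist.ravel()
    w = np.exp(-d ** 2 / (sigma[rows] * sigma[cols]))
    K = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
    K = K.maximum(K.T)
    deg = np.asarray(K.sum(axis=1)).ravel()
    dinv = sparse.diags(1.0 / np.sqrt(np.maximum(deg, 1e-12)))
    M = dinv @ K @ dinv
    k_eig = min(n_dms + 1, n - 1)
    v0 = np.full(n, 1.0 / np.sqrt(n))     # deterministic start vector
    vals, vecs = eigsh(M, k=k_eig, which="LA", v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # drop the trivial stationary component
    comps = vecs[:, 1:n_dms + 1] * vals[1:n_dms + 1]
    if comps.shape[1] < n_dms:
        comps = np.pad(comps, ((0, 0), (0, n_dms - comps.shape[1])))
    return comps


def embed_cells(ds: ad.AnnData, p: EmbedParams | None = None) -> ad.AnnData:
    """Compute the joint PCA + diffusion-map embedding and the symmetric kNN
    graph.  Stores ``obsm["X_embed"]`` (n_pcs + n_dms columns, each part
    variance-standardised) and ``obsp["knn"]`` (binary symmetric adjacency)."""
    p = p or EmbedParams()
    if p.k_neighbors >= ds.n_obs:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    X = ds.X.toarray() if sparse.issparse(ds.X) else np.asarray(ds.X)
    n_pcs = min(p.n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=p.seed)
    pcs = pca.fit_transform(X)
    if n_pcs < p.n_pcs:
        pcs = np.pad(pcs, ((0, 0), (0, p.n_pcs - n_pcs)))
    dms = _diffusion_components(pcs[:, :n_pcs], p.n_dms, p.bandwidth_neighbor)

    def block_scale(A: np.ndarray) -> np.ndarray:
        # scale each block to unit total variance so the PCA and DM parts
        # contribute comparably while keeping the within-block hierarchy
        total = A.var(axis=0).sum()
        return A / np.sqrt(total) if total > 0 else A

    embed = np.hstack([block_scale(pcs), block_scale(dms)])
    nn = NearestNeighbors(n_neighbors=p.k_neighbors + 1).fit(embed)
    _, idx = nn.kneighbors(embed)
    n = embed.shape[0]
    rows = np.repeat(np.arange(n), p.k_neighbors)
    cols = idx[:, 1:].ravel()
    A = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)
    ds.obsm["X_embed"] = embed
    ds.obsp["knn"] = A
    ds.uns["pca_variance_ratio"] = pca.explained_variance_ratio_
    return ds


def force_layout(graph: sparse.spmatrix, p: EmbedParams | None = None,
                 init: np.ndarray | None = None) -> np.ndarray:
    """ForceAtlas2-style 2-D layout: linear attraction along edges,
    degree-weighted 1/d repulsion between all node pairs, decaying step size,
    ``fle_iterations`` iterations.  Initialised from ``init`` (first two
    embedding dimensions) or a seeded random layout; a single node lands at
    the origin."""
    p = p or EmbedParams()
    A = sparse.csr_matrix(graph)
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return np.zeros((1, 2))
    rng = np.random.default_rng(p.seed)
    if init is not None:
        pos = np.asarray(init[:, :2], dtype=float).copy()
        pos -= pos.mean(axis=0)
        scale = np.abs(pos).max()
        if scale > 0:
            pos /= scale
    else:
        pos = rng.uniform(-1, 1, size=(n, 2))
    deg = np.asarray(A.sum(axis=1)).ravel() + 1.0
    src, dst = A.nonzero()
    k_rep = 1.0 / deg.mean() ** 2        # balances repulsion vs attraction
    chunk = max(1, int(2e6 // max(n, 1)))
    for it in range(p.fle_iterations):
        f = np.zeros_like(pos)
        # degree-weighted 1/d repulsion along the pair vector, chunked
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            diff = pos[sl, None, :] - pos[None, :, :]
            d2 = (diff ** 2).sum(axis=2) + 1e-9
            w = k_rep * deg[sl, None] * deg[None, :] / d2
            f[sl] += (w[:, :, None] * diff).sum(axis=1)
        # attraction: linear along each edge
        edge_vec = pos[dst] - pos[src]
        np.add.at(f, src, edge_vec)
        step = 0.1 / (1 + it * 0.02)
        norm = np.linalg.norm(f, axis=1, keepdims=True)
        pos += step * f / np.maximum(norm, 1.0)  # unit-capped displacement
    pos -= pos.mean(axis=0)
    return pos


def cluster_cells(graph: sparse.spmatrix, p: EmbedParams | None = None) -> np.ndarray:
    """Louvain community detection (multilevel) at the configured resolution.

    Cluster ids are 0..K-1 ordered by decreasing size; ties in the underlying
    optimisation are fixed by seeding igraph's RNG.
    """
    p = p or EmbedParams()
    A = sparse.coo_matrix(sparse.triu(sparse.csr_matrix(graph), k=1))
    g = igraph.Graph(n=A.shape[0],
                     edges=list(zip(A.row.tolist(), A.col.tolist())),
                     edge_attrs={"weight": A.data.astype(float).tolist()})
    import random as _random
    igraph.set_random_number_generator(_random.Random(p.seed))
    part = g.community_multilevel(weights="weight", resolution=p.resolution)
    labels = np.asarray(part.membership)
    # relabel by decreasing cluster size, stable on ties
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return np.array([remap[v] for v in labels])


def annotate_clusters(ds: ad.AnnData, clusters: np.ndarray,
                      somatic_es: np.ndarray,
                      developmental_es: np.ndarray) -> pd.DataFrame:
    """Label clusters SR (somatic-related), DR (developmental-related) or NA.

    A cluster is SR when its mean somatic enrichment exceeds the mean
    developmental enrichment and is positive, DR for the reverse, NA when
    neither mean is positive.  Within SR and DR, numbering follows ascending
    median sampling day.
    """
    if somatic_es is None or developmental_es is None:
        raise ValueError("per-cell enrichment scores are required")
    rows = []
    for cl in pd.unique(clusters):
        mask = clusters == cl
        s = float(np.mean(somatic_es[mask]))
        d = float(np.mean(developmental_es[mask]))
        if s > d and s > 0:
            group = "SR"
        elif d >= s and d > 0:
            group = "DR"
        else:
            group = "NA"
        med_day = float(ds.obs["day"][mask].median()) if "day" in ds.obs else 0.0
        rows.append({"cluster": cl, "group": group, "somatic_es": s,
                     "developmental_es": d, "median_day": med_day,
                     "n_cells": int(mask.sum())})
    df = pd.DataFrame(rows)
    for group in ("SR", "DR"):
        sub = df[df["group"] == group].sort_values(
            ["median_day", "cluster"], kind="stable")
        for i, ix in enumerate(sub.index, start=1):
            df.loc[ix, "label"] = f"{group}{i}"
    df.loc[df["group"] == "NA", "label"] = "NA"
    return df.set_index("cluster")
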