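"""Secretome (TMT proteomics) processing stage.

Implements the conditioned-medium pipeline: contaminant removal, the
at-least-2-of-3-replicates filter, single-missing-value imputation by the mean
of the two observed replicates, normalisation by per-sample protein amount
(BCA) followed by per-replicate median scaling, Student t-tests between
time-window pairs with exclusion of proteins maximal only in the first window
(serum residue), restriction to annotated secreted proteins, z-scored profile
clustering (Euclidean / complete linkage) and mean-centred PCA of the samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datasets import GeneSetCollection, SecretomePanel

log = logging.getLogger(__name__)

__all__ = [
    "SecretomeParams", "preprocess_panel", "differential_accumulation",
    "select_secreted", "cluster_profiles", "pca_panel",
]


@dataclass
class SecretomeParams:
    min_replicates_present: int = 2
    n_replicates: int = 3
    diff_alpha: float = 0.05
    exclude_first_window_max: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_replicates_present <= self.n_replicates:
            raise ValueError("min_replicates_present out of range")
        if not 0 < self.diff_alpha < 1:
            raise ValueError("diff_alpha must be in (0, 1)")


def preprocess_panel(panel: SecretomePanel,
                     params: SecretomeParams | None = None) -> SecretomePanel:
    """Filter, impute and normalise the raw panel.

    Steps, in order: drop flagged contaminants; drop proteins observed in
    fewer than ``min_replicates_present`` replicates at *every* window; impute
    a single missing replicate per (protein, window) as the mean of the other
    observed replicates; divide each sample by its protein amount (ug); scale
    each replicate's distribution by its median (post-scaling replicate
    medians are exactly 1).

    A (protein, window) cell with >=2 missing replicates is left missing and
    the protein is reported via logging, never silently imputed.
    """
    params = params or SecretomeParams()
    panel = panel.copy()

    if "contaminant" in panel.flags:
        keep = ~panel.flags["contaminant"].to_numpy(dtype=bool)
        panel = panel.subset(panel.proteins[keep])

    present = (~panel.missing_mask).sum(axis=2)           # proteins x windows
    retained = (present >= params.min_replicates_present).any(axis=1)
    panel = panel.subset(panel.proteins[retained])

    panel = impute_missing(panel)
    cube = panel.intensities
    cube /= panel.amounts[None, :, :]                     # BCA normalisation
    for r in range(cube.shape[2]):
        med = np.nanmedian(cube[:, :, r])
        if med > 0:
            cube[:, :, r] /= med
    return panel


def impute_missing(panel: SecretomePanel) -> SecretomePanel:
    """Impute a single missing replicate per (protein, window) as the mean of
    the other observed replicates.  Cells with >=2 missing replicates are
    left missing and the protein is reported via logging."""
    cube = panel.intensities
    present = ~np.isnan(cube)
    n_present = present.sum(axis=2)
    one_missing = n_present == cube.shape[2] - 1
    if one_missing.any():
        with np.errstate(invalid="ignore"):
            means = np.nanmean(cube, axis=2)
        pi, wi = np.where(one_missing)
        for p, w in zip(pi, wi):
            ri = np.where(~present[p, w])[0][0]
            cube[p, w, ri] = means[p, w]
    multi_missing = (n_present <= cube.shape[2] - 2) & (n_present > 0)
    for p in np.unique(np.where(multi_missing)[0]):
        log.warning("protein %s has >=2 missing replicates at some window; "
                    "left missing", panel.proteins[p])
    return panel


@dataclass
class DiffRecord:
    protein: str
    window_a: str
    window_b: str
    t: float
    p: float
    direction: str
    degenerate: bool
    passes: bool


def differential_accumulation(panel: SecretomePanel,
                              params: SecretomeParams | None = None,
                              pairs: list[tuple[str, str]] | None = None,
                              ) -> pd.DataFrame:
    """Two-sample Student t-test (equal variance, n = replicates) per protein
    per window pair.

    Proteins whose replicate-mean profile is *strictly* maximal at the first
    window are excluded beforehand (serum-residual heuristic); ties with a
    later window do not exclude.  Zero variance in both groups with equal
    means yields p = 1 with a ``degenerate`` flag.
    """
    params = params or SecretomeParams()
    if pairs is None:
        pairs = [(panel.windows[i], panel.windows[i + 1])
                 for i in range(len(panel.windows) - 1)]

    keep = np.ones(len(panel.proteins), dtype=bool)
    if params.exclude_first_window_max and len(panel.windows) > 1:
        means = panel.replicate_means()
        with np.errstate(invalid="ignore"):
            first_strict_max = np.all(means[:, :1] > means[:, 1:], axis=1)
        keep &= ~first_strict_max
    sub = panel.subset(panel.proteins[keep])

    w_idx = {w: i for i, w in enumerate(sub.windows)}
    records: list[DiffRecord] = []
    for wa, wb in pairs:
        a = sub.intensities[:, w_idx[wa], :]
        b = sub.intensities[:, w_idx[wb], :]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(b, a, axis=1, equal_var=True,
                                   nan_policy="omit")
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        degen = ~np.isfinite(p)
        p = np.where(degen, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)
        with np.errstate(invalid="ignore"):
            diff = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
        for i, prot in enumerate(sub.proteins):
            records.append(DiffRecord(
                protein=prot, window_a=wa, window_b=wb,
                t=float(t[i]), p=float(p[i]),
                direction="up" if diff[i] > 0 else "down",
                degenerate=bool(degen[i]),
                passes=bool(p[i] < params.diff_alpha),
            ))
    df = pd.DataFrame([r.__dict__ for r in records])
    return df


def select_secreted(panel: SecretomePanel,
                    annotation: GeneSetCollection | list[str]) -> SecretomePanel:
    """Restrict the panel to proteins annotated as secreted."""
    if isinstance(annotation, GeneSetCollection):
        secreted: set[str] = set()
        for name in annotation.names():
            if annotation.roles.get(name) == "secreted":
                secreted.update(annotation[name])
        if not secreted:
            for name in annotation.names():
                secreted.update(annotation[name])
    else:
        secreted = set(annotation)
    keep = [p for p in panel.proteins if p in secreted]
    if not keep:
        log.warning("secreted annotation does not intersect the panel")
    out = panel.subset(keep)
    log.info("select_secreted: retained %d of %d proteins",
             len(out.proteins), len(panel.proteins))
    return out


def _zscore_profiles(panel: SecretomePanel) -> np.ndarray:
    """Per-protein z-scored window profile of replicate means; constant
    profiles become all-zero."""
    prof = panel.replicate_means()
    mean = np.nanmean(prof, axis=1, keepdims=True)
    sd = np.nanstd(prof, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (prof - mean) / sd
    z[~np.isfinite(z)] = 0.0
    return z


def cluster_profiles(panel: SecretomePanel) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical clustering of z-scored profiles (Euclidean distance,
    complete linkage).  Returns ``(leaf_order, linkage_matrix)`` with a
    deterministic leaf order."""
    if len(panel.proteins) < 2:
        raise ValueError("need at least 2 proteins to cluster")
    z = _zscore_profiles(panel)
    link = hierarchy.linkage(pdist(z, metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(link)
    return order, link


def pca_panel(panel: SecretomePanel) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the (window, replicate) samples on mean-centred intensities
    (no variance scaling).

    Returns a coordinates DataFrame indexed by sample and the explained
    variance fractions.  Component signs are fixed so that the
    largest-magnitude protein loading of each component is positive.
    """
    n_p, n_w, n_r = panel.intensities.shape
    n_samples = n_w * n_r
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = panel.intensities.reshape(n_p, n_samples).T       # samples x proteins
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: per component, largest-|loading| positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U * S
    var = S ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    labels = [f"{w}|rep{r + 1}" for w in panel.windows for r in range(n_r)]
    df = pd.DataFrame(coords, index=pd.Index(labels, name="sample"),
                      columns=[f"PC{k + 1}" for k in range(coords.shape[1])])
    return df, evr
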