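"""Core data containers and standard-format I/O.

Single-cell data lives in :class:`anndata.AnnData` (cells x genes, raw counts
in ``layers["counts"]``, log2-CPM in ``X`` after normalisation).  The secretome
is a dense protein x window x replicate intensity cube with an explicit
missing-value mask, plus per-sample protein amounts (BCA quantification, ug)
and per-protein annotation flags.  Gene sets are plain named lists with a role
tag (signature, phase, target, ligand/receptor annotation, validated pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

import anndata as ad

__all__ = [
    "GeneSetCollection",
    "SecretomePanel",
    "read_gmt",
    "write_gmt",
    "read_10x_dir",
    "write_10x_dir",
    "read_secretome_csv",
    "read_pair_csv",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


# ---------------------------------------------------------------------------
# Gene sets


@dataclass
class GeneSetCollection:
    """Named gene lists with an optional role per set.

    Roles distinguish how a set is used downstream: ``"signature"`` (per-cell
    enrichment), ``"phase"`` (cell-cycle scoring), ``"target"`` (pathway target
    activation), ``"secreted"`` / ``"ligand"`` / ``"receptor"`` (annotation
    universes), ``"sasp"``.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, genes: Sequence[str], description: str = "",
            role: str = "signature") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name: {name!r}")
        self.sets[name] = list(genes)
        self.descriptions[name] = description
        self.roles[name] = role

    def subset(self, role: str) -> "GeneSetCollection":
        out = GeneSetCollection()
        for name, genes in self.sets.items():
            if self.roles.get(name) == role:
                out.add(name, genes, self.descriptions.get(name, ""), role)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, genes...).

    Raises :class:`FormatError` for lines with fewer than 3 fields or
    duplicated set names, naming the offending line.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}")
            name, desc, *genes = fields
            if name in coll:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate gene set name {name!r}")
            coll.add(name, [g for g in genes if g], desc)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Secretome panel


@dataclass
class SecretomePanel:
    """TMT-style secretome panel: protein x time-window x replicate.

    ``intensities`` holds non-negative reals with NaN marking missing values.
    ``amounts`` is the per-(window, replicate) total protein amount in ug used
    for BCA normalisation.  ``flags`` is a boolean DataFrame indexed by protein
    with columns such as ``contaminant``, ``secreted``, ``ligand``, ``sasp``,
    ``serum_residual``.
    """

    proteins: pd.Index
    windows: list[str]
    intensities: np.ndarray          # (n_proteins, n_windows, n_replicates)
    amounts: np.ndarray              # (n_windows, n_replicates), ug
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        self.proteins = pd.Index(self.proteins)
        n_p, n_w, n_r = self.intensities.shape
        if n_p != len(self.proteins) or n_w != len(self.windows):
            raise ValueError("intensity cube shape does not match labels")
        if self.amounts.shape != (n_w, n_r):
            raise ValueError("amounts shape must be (n_windows, n_replicates)")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValueError("intensities must be non-negative")
        if np.any(self.amounts <= 0):
            raise ValueError("protein amounts must be positive")

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[2]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.intensities)

    def replicate_means(self) -> np.ndarray:
        """Per-protein per-window mean over observed replicates."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.intensities, axis=2)

    def subset(self, proteins: Iterable[str]) -> "SecretomePanel":
        keep = self.proteins.isin(list(proteins))
        return SecretomePanel(
            proteins=self.proteins[keep],
            windows=list(self.windows),
            intensities=self.intensities[keep].copy(),
            amounts=self.amounts.copy(),
            flags=self.flags.loc[self.proteins[keep]].copy(),
        )

    def copy(self) -> "SecretomePanel":
        return SecretomePanel(self.proteins.copy(), list(self.windows),
                              self.intensities.copy(), self.amounts.copy(),
                              self.flags.copy())

    # -- long-format CSV round trip -------------------------------------
    def to_long(self) -> pd.DataFrame:
        n_p, n_w, n_r = self.intensities.shape
        pi, wi, ri = np.meshgrid(np.arange(n_p), np.arange(n_w),
                                 np.arange(n_r), indexing="ij")
        df = pd.DataFrame({
            "protein": self.proteins.values[pi.ravel()],
            "window": np.asarray(self.windows)[wi.ravel()],
            "replicate": ri.ravel() + 1,
            "intensity": self.intensities.ravel(),
            "amount_ug": self.amounts[wi.ravel(), ri.ravel()],
        })
        return df[~df["intensity"].isna()].reset_index(drop=True)

    def to_csv(self, path: str | Path, flags_path: str | Path | None = None) -> None:
        self.to_long().to_csv(path, index=False)
        if flags_path is not None:
            self.flags.to_csv(flags_path, index_label="protein")


def read_secretome_csv(path: str | Path,
                       flags_path: str | Path | None = None) -> SecretomePanel:
    """Read a long-format secretome CSV (protein, window, replicate,
    intensity, amount_ug).  Windows are ordered by first appearance; absent
    (protein, window, replicate) rows become missing values."""
    df = pd.read_csv(path)
    required = {"protein", "window", "replicate", "intensity", "amount_ug"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    windows = list(pd.unique(df["window"]))
    proteins = pd.Index(pd.unique(df["protein"]))
    reps = sorted(df["replicate"].unique())
    n_r = len(reps)
    cube = np.full((len(proteins), len(windows), n_r), np.nan)
    amounts = np.full((len(windows), n_r), np.nan)
    p_idx = pd.Series(np.arange(len(proteins)), index=proteins)
    w_idx = {w: i for i, w in enumerate(windows)}
    r_idx = {r: i for i, r in enumerate(reps)}
    pi = p_idx[df["protein"]].to_numpy()
    wi = df["window"].map(w_idx).to_numpy()
    ri = df["replicate"].map(r_idx).to_numpy()
    cube[pi, wi, ri] = df["intensity"].to_numpy()
    amounts[wi, ri] = df["amount_ug"].to_numpy()
    if np.isnan(amounts).any():
        # samples with no observed protein at all: fall back to column mean
        col_mean = np.nanmean(amounts)
        amounts = np.where(np.isnan(amounts), col_mean, amounts)
    if flags_path is not None and Path(flags_path).exists():
        flags = pd.read_csv(flags_path, index_col="protein").astype(bool)
        flags = flags.reindex(proteins, fill_value=False)
    else:
        flags = pd.DataFrame(index=proteins)
    return SecretomePanel(proteins, windows, cube, amounts, flags)


# ---------------------------------------------------------------------------
# 10X-style directory I/O


def write_10x_dir(adata: ad.AnnData, dir_path: str | Path) -> None:
    """Write a 10X-style directory: matrix.mtx (genes as rows), barcodes.tsv,
    features.tsv, plus cell_meta.tsv with the per-cell metadata."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mat = sparse.csr_matrix(counts).T.tocoo()  # genes x cells
    spio.mmwrite(dir_path / "matrix.mtx", mat, field="integer")
    pd.Series(adata.obs_names).to_csv(dir_path / "barcodes.tsv",
                                      index=False, header=False)
    feats = pd.DataFrame({
        "gene_id": adata.var_names,
        "gene_name": adata.var_names,
        "feature_type": "Gene Expression",
    })
    feats.to_csv(dir_path / "features.tsv", sep="\t", index=False, header=False)
    meta_cols = [c for c in ("day", "replicate", "trajectory") if c in adata.obs]
    meta = adata.obs[meta_cols].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(dir_path / "cell_meta.tsv", sep="\t", index=False)


def read_10x_dir(dir_path: str | Path) -> ad.AnnData:
    """Read a 10X-style directory (matrix.mtx genes-as-rows, barcodes.tsv,
    features.tsv, optional cell_meta.tsv) into AnnData with counts in
    ``layers["counts"]``.

    Validates: non-negative integer entries, unique barcodes.
    """
    dir_path = Path(dir_path)
    try:
        mat = spio.mmread(dir_path / "matrix.mtx")
    except Exception as exc:  # malformed header etc.
        raise FormatError(f"{dir_path}/matrix.mtx: {exc}") from exc
    mat = sparse.csr_matrix(mat.T)  # cells x genes
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{dir_path}/matrix.mtx: negative entry in count matrix")
    if mat.nnz and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"{dir_path}/matrix.mtx: non-integer entry in count matrix")
    barcodes = pd.read_csv(dir_path / "barcodes.tsv", header=None)[0].astype(str)
    if barcodes.duplicated().any():
        dup = barcodes[barcodes.duplicated()].iloc[0]
        raise FormatError(f"{dir_path}/barcodes.tsv: duplicated barcode {dup!r}")
    feats = pd.read_csv(dir_path / "features.tsv", sep="\t", header=None)
    genes = feats[1 if feats.shape[1] > 1 else 0].astype(str)
    if mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"{dir_path}: matrix shape {mat.shape[::-1]} does not match "
            f"{len(genes)} features x {len(barcodes)} barcodes")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = dir_path / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("barcode")
        obs = obs.join(meta)
    var = pd.DataFrame(index=pd.Index(genes.values, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    adata = ad.AnnData(X=mat.astype(np.float32), obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    return adata


def read_pair_csv(path: str | Path) -> pd.DataFrame:
    """Read a two-column (ligand, receptor) CSV of gene symbols."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (ligand, receptor)")
    df = df.iloc[:, :2]
    df.columns = ["ligand", "receptor"]
    return df


def read_gene_list_csv(path: str | Path) -> list[str]:
    """Read a one-column CSV of gene symbols (header optional)."""
    df = pd.read_csv(path)
    return df.iloc[:, 0].astype(str).tolist()


def save_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
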