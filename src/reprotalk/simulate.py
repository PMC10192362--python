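"""Synthetic multi-omic time-course generator with planted ground truth.

Emulates the statistical structure of a microfluidic reprogramming
experiment sampled at day 0, day 3 and then every 48 h to day 15:

* negative-binomial scRNA-seq counts with per-cell log-normal library factors;
* a single somatic population that branches mid-course into a
  secretory-somatic and a developmental (reprogramming) trajectory;
* planted gene signatures (somatic, developmental, matrisome,
  late-pluripotency, cell-cycle phases, apoptosis, SASP, pathway targets)
  switched on in a (trajectory, day-window) block as log2 mean shifts;
* planted ligand-receptor pairs whose ligand is up in the source trajectory
  and receptor in the target trajectory during a day window;
* a fraction of cells violating QC (high mitochondrial load or collapsed
  library) so the QC stage has something to remove;
* a 3-replicate TMT-style secretome over 2-day windows with missing values,
  contaminants and serum-residual proteins maximal in the first window.

Every random draw flows from ``SimConfig.seed`` through one
``numpy.random.Generator``, so a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

import anndata as ad

from .datasets import GeneSetCollection, SecretomePanel, write_10x_dir, write_gmt

__all__ = [
    "SimConfig", "SignatureSpec", "PlantedPair", "SecretomeSpec",
    "GroundTruth", "simulate_cells", "simulate_secretome", "write_fixture",
]

SOMATIC = "somatic"          # shared pre-branch state
SECRETORY = "secretory"      # somatic-secretory branch
DEVELOPMENTAL = "developmental"  # reprogramming branch


@dataclass
class SignatureSpec:
    """A planted gene signature: ``n_genes`` genes up-shifted by
    ``log2_effect`` in cells of ``trajectory`` during ``active_day_window``
    (inclusive day range)."""
    set_name: str
    n_genes: int
    log2_effect: float
    trajectory: str | tuple[str, ...]   # "all" targets every cell
    active_day_window: tuple[int, int]
    baseline: str = "high"              # "high": graded shift on a detected
                                        # gene; "low": on/off lineage marker
                                        # (rare baseline, strong activation)
    ramp: bool = False                  # ramp the log2 effect linearly from
                                        # half to full across the day window

    def effect_at(self, day: int) -> float:
        lo, hi = self.active_day_window
        if not self.ramp or hi <= lo:
            return self.log2_effect
        return self.log2_effect * (0.5 + 0.5 * (day - lo) / (hi - lo))

    def labels(self) -> set[str]:
        if self.trajectory == "all":
            return {SOMATIC, SECRETORY, DEVELOPMENTAL}
        if isinstance(self.trajectory, str):
            return {self.trajectory}
        return set(self.trajectory)


@dataclass
class PlantedPair:
    ligand: str
    receptor: str
    source_trajectory: str
    target_trajectory: str
    log2_effect: float
    day_window: tuple[int, int]


@dataclass
class SecretomeSpec:
    n_proteins: int = 120
    n_windows: int = 7                  # D1-D2 ... D13-D14
    n_secretome_replicates: int = 3
    missing_rate: float = 0.05
    contaminant_count: int = 8
    serum_residual_count: int = 5
    planted_dynamic_count: int = 12
    sparse_count: int = 5               # fail the >=2-replicate filter by design
    dynamic_log2_effect: float = 1.5
    noise_sigma: float = 0.12           # natural-log multiplicative replicate noise
    base_amount_ug: float = 40.0


def _default_signatures() -> list[SignatureSpec]:
    # Effects are lineage-marker scale (4-8x) so the planted structure is
    # recoverable at the enrichment thresholds the analysis uses.
    return [
        SignatureSpec("Somatic", 80, 6.0, (SOMATIC, SECRETORY), (0, 15),
                      baseline="low"),
        SignatureSpec("Developmental", 80, 6.0, DEVELOPMENTAL, (0, 15),
                      baseline="low"),
        SignatureSpec("Matrisome", 30, 8.0, SECRETORY, (13, 15), baseline="low"),
        SignatureSpec("LatePluripotency", 30, 8.0, DEVELOPMENTAL, (13, 15),
                      baseline="low"),
        SignatureSpec("SASP", 20, 2.0, SECRETORY, (9, 15)),
        SignatureSpec("Apoptosis", 20, 0.25, SECRETORY, (9, 15)),
        SignatureSpec("STAT3_targets", 25, 2.5, DEVELOPMENTAL, (7, 15)),
    ]


def _default_pairs() -> list[PlantedPair]:
    return [PlantedPair("LIG1", "REC1", SECRETORY, DEVELOPMENTAL, 1.0, (9, 15))]


@dataclass
class SimConfig:
    seed: int = 0
    days: tuple[int, ...] = (0, 3, 5, 7, 9, 11, 13, 15)
    cells_per_day: int = 1600           # per day per replicate
    n_replicates: int = 2
    n_genes: int = 500
    nb_mean_range: tuple[float, float] = (0.05, 4.0)
    nb_dispersion: float = 2.0
    library_size_lognormal: tuple[float, float] = (0.0, 0.25)
    mito_gene_fraction: float = 0.05
    mito_expr_fraction: float = 0.04    # expected mito share of a healthy cell
    branch_day: int = 7
    trajectory_mix: float = 0.5         # fraction secretory after the branch
    qc_violator_fraction: float = 0.04
    n_drift_genes: int = 60
    drift_log2: float = 1.5
    n_phase_genes: int = 20
    phase_log2_effect: float = 2.0
    phase_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)  # G1, S, G2M
    signature_specs: list[SignatureSpec] = field(default_factory=_default_signatures)
    planted_pairs: list[PlantedPair] = field(default_factory=_default_pairs)
    n_decoy_ligands: int = 8
    n_decoy_receptors: int = 8
    n_decoy_validated: int = 10
    secretome: SecretomeSpec = field(default_factory=SecretomeSpec)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.cells_per_day <= 0 or self.n_replicates <= 0:
            raise ValueError("dimensions must be positive")
        days = list(self.days)
        if days != sorted(days) or len(set(days)) != len(days):
            raise ValueError("days must be strictly increasing")
        if self.branch_day not in days:
            raise ValueError("branch_day must be one of the sampling days")
        for frac in (self.mito_gene_fraction, self.trajectory_mix,
                     self.qc_violator_fraction, self.mito_expr_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for s in self.signature_specs:
            if not np.isfinite(s.log2_effect):
                raise ValueError(f"non-finite effect for {s.set_name}")
        if self.secretome.missing_rate >= 2 / 3:
            raise ValueError("missing_rate >= 2/3 would defeat the replicate filter")
        if self.nb_mean_range[0] <= 0 or self.nb_dispersion <= 0:
            raise ValueError("NB parameters must be positive")


@dataclass
class GroundTruth:
    """Planted truth for every cell, gene, pair and secretome protein."""
    cell_trajectory: pd.Series            # barcode -> label
    cell_phase: pd.Series                 # barcode -> G1/S/G2M
    gene_signatures: dict[str, list[str]]  # set name -> member genes
    planted_pairs: list[PlantedPair]
    secretome_class: dict[str, str]       # protein -> class
    baseline_means: pd.Series             # gene -> NB baseline mean

    def to_json(self, path: str | Path) -> None:
        obj = {
            "cell_trajectory": self.cell_trajectory.to_dict(),
            "cell_phase": self.cell_phase.to_dict(),
            "gene_signatures": self.gene_signatures,
            "planted_pairs": [asdict(p) for p in self.planted_pairs],
            "secretome_class": self.secretome_class,
            "baseline_means": self.baseline_means.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            cell_trajectory=pd.Series(obj["cell_trajectory"]),
            cell_phase=pd.Series(obj["cell_phase"]),
            gene_signatures=obj["gene_signatures"],
            planted_pairs=[PlantedPair(**{**p, "day_window": tuple(p["day_window"])})
                           for p in obj["planted_pairs"]],
            secretome_class=obj["secretome_class"],
            baseline_means=pd.Series(obj["baseline_means"]),
        )


# ---------------------------------------------------------------------------
# gene namespace


def _allocate_genes(config: SimConfig, rng: np.random.Generator):
    """Assign names and roles to the gene index; returns (names, roles dict)."""
    n = config.n_genes
    n_mito = int(round(config.mito_gene_fraction * n))
    names: list[str] = [f"MT-G{i + 1}" for i in range(n_mito)]
    cursor = n_mito

    def take(count: int, prefix: str | None = None) -> list[str]:
        nonlocal cursor
        if cursor + count > n:
            raise ValueError("n_genes too small for the requested planted structure")
        if prefix is None:
            out = [f"G{cursor + i + 1:04d}" for i in range(count)]
        else:
            out = [f"{prefix}{i + 1}" for i in range(count)]
        cursor += count
        names.extend(out)
        return out

    sig_genes = {s.set_name: take(s.n_genes) for s in config.signature_specs}
    sig_genes["SPhase"] = take(config.n_phase_genes)
    sig_genes["G2MPhase"] = take(config.n_phase_genes)
    drift = take(config.n_drift_genes)
    lig, rec = [], []
    for p in config.planted_pairs:
        names.append(p.ligand); lig.append(p.ligand); cursor += 1
        names.append(p.receptor); rec.append(p.receptor); cursor += 1
    decoy_lig = take(config.n_decoy_ligands, "DLIG")
    decoy_rec = take(config.n_decoy_receptors, "DREC")
    take(n - cursor)  # background filler
    assert len(names) == n
    return names, {
        "signatures": sig_genes, "drift": drift,
        "ligands": lig, "receptors": rec,
        "decoy_ligands": decoy_lig, "decoy_receptors": decoy_rec,
        "n_mito": n_mito,
    }


# ---------------------------------------------------------------------------
# single-cell simulation


def simulate_cells(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw the single-cell count matrix and its ground truth.

    Counts are gamma-Poisson (negative binomial with mean ``m`` and
    dispersion ``theta``, variance ``m + m^2/theta``), with the per-gene mean
    composed as baseline x signature block shifts x day drift x phase shift
    x per-cell library factor.
    """
    rng = np.random.default_rng(config.seed)
    names, roles = _allocate_genes(config, rng)
    n_genes = config.n_genes
    gene_idx = {g: i for i, g in enumerate(names)}

    lo, hi = config.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    # planted genes get upper-half baselines so shifts are not drowned by
    # shot noise at near-zero counts
    planted = set()
    low_baseline = set()
    for s in config.signature_specs:
        genes = roles["signatures"][s.set_name]
        if s.baseline == "low":
            low_baseline.update(genes)
        else:
            planted.update(genes)
    planted.update(roles["signatures"]["SPhase"])
    planted.update(roles["signatures"]["G2MPhase"])
    planted.update(roles["ligands"]); planted.update(roles["receptors"])
    # sorted iteration: gene-to-baseline assignment must not depend on set
    # (hash) ordering, or fixed seeds stop reproducing across processes
    planted_ix = np.array(sorted(gene_idx[g] for g in planted))
    base[planted_ix] = np.exp(rng.uniform(np.log(np.sqrt(lo * hi)), np.log(hi),
                                          size=planted_ix.size))
    if low_baseline:
        # on/off lineage markers: rarely detected at baseline so that the
        # activated state is strongly enriched in z-score terms
        low_ix = np.array(sorted(gene_idx[g] for g in low_baseline))
        base[low_ix] = lo
    # scale mito genes to the configured expression share
    n_mito = roles["n_mito"]
    if n_mito:
        mito_sum = base[:n_mito].sum()
        rest_sum = base[n_mito:].sum()
        target = config.mito_expr_fraction
        base[:n_mito] *= target * rest_sum / ((1 - target) * max(mito_sum, 1e-12))

    days = list(config.days)
    n_per = config.cells_per_day
    cells = []
    for day in days:
        for rep in range(1, config.n_replicates + 1):
            for i in range(n_per):
                cells.append((day, rep))
    n_cells = len(cells)
    day_arr = np.array([c[0] for c in cells])
    rep_arr = np.array([c[1] for c in cells])

    # trajectory labels: one shared state up to the branch day, two after
    labels = np.full(n_cells, SOMATIC, dtype=object)
    post = day_arr > config.branch_day
    is_secr = rng.random(n_cells) < config.trajectory_mix
    labels[post & is_secr] = SECRETORY
    labels[post & ~is_secr] = DEVELOPMENTAL

    phases = rng.choice(["G1", "S", "G2M"], size=n_cells,
                        p=list(config.phase_fractions))

    mu_lib, sd_lib = config.library_size_lognormal
    lib = rng.lognormal(mu_lib, sd_lib, size=n_cells)

    # QC violators: half high-mito, half collapsed library
    viol = np.full(n_cells, "none", dtype=object)
    u = rng.random(n_cells)
    half = config.qc_violator_fraction / 2
    viol[u < half] = "mito"
    viol[(u >= half) & (u < 2 * half)] = "lowdepth"
    lib = np.where(viol == "lowdepth", lib * 0.03, lib)

    # per-gene log2 multiplier per (day, label, phase, mito-violation) block
    drift_ix = np.array([gene_idx[g] for g in roles["drift"]])
    day_rank = {d: i for i, d in enumerate(days)}

    def block_mean(day: int, label: str, phase: str, mito_viol: bool) -> np.ndarray:
        m = base.copy()
        for s in config.signature_specs:
            loD, hiD = s.active_day_window
            if label in s.labels() and loD <= day <= hiD:
                ix = [gene_idx[g] for g in roles["signatures"][s.set_name]]
                m[ix] *= 2.0 ** s.effect_at(day)
        for p in config.planted_pairs:
            loD, hiD = p.day_window
            if loD <= day <= hiD:
                if label == p.source_trajectory:
                    m[gene_idx[p.ligand]] *= 2.0 ** p.log2_effect
                if label == p.target_trajectory:
                    m[gene_idx[p.receptor]] *= 2.0 ** p.log2_effect
        if phase == "S":
            ix = [gene_idx[g] for g in roles["signatures"]["SPhase"]]
            m[ix] *= 2.0 ** config.phase_log2_effect
        elif phase == "G2M":
            ix = [gene_idx[g] for g in roles["signatures"]["G2MPhase"]]
            m[ix] *= 2.0 ** config.phase_log2_effect
        if drift_ix.size:
            frac = day_rank[day] / max(len(days) - 1, 1)
            m[drift_ix] *= 2.0 ** (config.drift_log2 * frac)
        if mito_viol and roles["n_mito"]:
            m[:roles["n_mito"]] *= 8.0
        return m

    theta = config.nb_dispersion
    counts = sparse.lil_matrix((1, 1))  # placeholder
    blocks = []
    order = []
    keys = pd.DataFrame({"day": day_arr, "label": labels, "phase": phases,
                         "mv": viol == "mito"})
    for (day, label, phase, mv), sub in keys.groupby(
            ["day", "label", "phase", "mv"], sort=True):
        ix = sub.index.to_numpy()
        m = block_mean(int(day), label, phase, bool(mv))
        mu = lib[ix, None] * m[None, :]
        lam = rng.gamma(theta, mu / theta)
        x = rng.poisson(lam)
        blocks.append(sparse.csr_matrix(x))
        order.append(ix)
    order = np.concatenate(order)
    counts = sparse.vstack(blocks).tocsr()
    inv = np.empty_like(order)
    inv[order] = np.arange(n_cells)
    counts = counts[inv]

    barcodes = [f"CELL{i + 1:06d}" for i in range(n_cells)]
    obs = pd.DataFrame({
        "day": day_arr, "replicate": rep_arr, "trajectory": labels,
        "phase_true": phases, "lib_factor": lib, "qc_violation": viol,
    }, index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(index=pd.Index(names, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    var["baseline_mean"] = base
    adata = ad.AnnData(X=counts.astype(np.float32), obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    adata.uns["sim_roles"] = {k: v for k, v in roles.items() if k != "signatures"}

    truth = GroundTruth(
        cell_trajectory=obs["trajectory"].copy(),
        cell_phase=obs["phase_true"].copy(),
        gene_signatures={k: list(v) for k, v in roles["signatures"].items()},
        planted_pairs=list(config.planted_pairs),
        secretome_class={},
        baseline_means=pd.Series(base, index=names),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# secretome simulation


def _window_labels(n_windows: int) -> list[str]:
    return [f"D{2 * w + 1}-D{2 * w + 2}" for w in range(n_windows)]


def _windows_for_days(day_window: tuple[int, int], n_windows: int) -> list[int]:
    """Secretome windows (0-based) overlapping an inclusive day range."""
    lo, hi = day_window
    out = []
    for w in range(n_windows):
        w_lo, w_hi = 2 * w + 1, 2 * w + 2
        if w_lo <= hi and w_hi >= lo:
            out.append(w)
    return out


def simulate_secretome(config: SimConfig, truth: GroundTruth) -> SecretomePanel:
    """Draw the 3-replicate secretome panel and record protein classes in
    ``truth.secretome_class``.

    Classes: ``secreted-dynamic`` (planted ligands plus extra proteins with a
    ramp or pulse profile), ``flat``, ``serum-residual`` (strictly maximal in
    the first window), ``contaminant`` and ``sparse`` (observed in a single
    replicate everywhere, so the >=2-replicate filter removes them).
    """
    spec = config.secretome
    rng = np.random.default_rng(config.seed + 1_000_003)
    W = spec.n_windows
    R = spec.n_secretome_replicates
    windows = _window_labels(W)

    ligands = [p.ligand for p in config.planted_pairs]
    n_extra_dyn = max(spec.planted_dynamic_count - len(ligands), 0)
    decoy_lig = list(truth.baseline_means.index[
        truth.baseline_means.index.str.startswith("DLIG")])
    proteins: list[str] = []
    classes: dict[str, str] = {}
    for g in ligands:
        proteins.append(g); classes[g] = "secreted-dynamic"
    for i in range(n_extra_dyn):
        name = f"DYN{i + 1}"
        proteins.append(name); classes[name] = "secreted-dynamic"
    for g in decoy_lig:
        proteins.append(g); classes[g] = "flat"
    for i in range(spec.serum_residual_count):
        name = f"SERUM{i + 1}"
        proteins.append(name); classes[name] = "serum-residual"
    for i in range(spec.contaminant_count):
        name = f"KRT{i + 1}"
        proteins.append(name); classes[name] = "contaminant"
    for i in range(spec.sparse_count):
        name = f"SPARSE{i + 1}"
        proteins.append(name); classes[name] = "sparse"
    n_named = len(proteins)
    if n_named > spec.n_proteins:
        raise ValueError("n_proteins too small for the planted structure")
    for i in range(spec.n_proteins - n_named):
        name = f"P{i + 1:04d}"
        proteins.append(name); classes[name] = "flat"

    n_p = len(proteins)
    base = rng.lognormal(np.log(1e6), 0.8, size=n_p)
    profile = np.ones((n_p, W))
    eff = spec.dynamic_log2_effect
    for i, prot in enumerate(proteins):
        cls = classes[prot]
        if cls == "secreted-dynamic":
            pair = next((p for p in config.planted_pairs if p.ligand == prot), None)
            if pair is not None:
                act = _windows_for_days(pair.day_window, W)
                profile[i, act] = 2.0 ** pair.log2_effect
            elif rng.random() < 0.5:      # monotone ramp
                profile[i] = 2.0 ** (eff * np.arange(W) / (W - 1))
            else:                         # pulse in the mid-course
                peak = rng.integers(2, W - 1)
                profile[i] = 2.0 ** (eff * np.exp(-0.5 * ((np.arange(W) - peak) / 1.0) ** 2))
        elif cls == "serum-residual":
            profile[i] = 2.0 ** (-1.0 * np.arange(W))   # strict max at window 1

    noise = rng.lognormal(0.0, spec.noise_sigma, size=(n_p, W, R))
    cube = base[:, None, None] * profile[:, :, None] * noise

    # per-sample protein amounts (BCA), ug
    amounts = spec.base_amount_ug * rng.lognormal(0.0, 0.05, size=(W, R))

    # missing values: survivors lose at most one replicate per window
    survivor = np.array([classes[p] != "sparse" for p in proteins])
    if spec.missing_rate > 0:
        drop = rng.random((n_p, W, R)) < spec.missing_rate
        n_drop = drop.sum(axis=2)
        # cap survivor losses at one replicate per (protein, window)
        for pi, wi in zip(*np.where((n_drop >= 2) & survivor[:, None])):
            keep_one = np.where(drop[pi, wi])[0]
            spare = rng.choice(keep_one, size=keep_one.size - 1, replace=False)
            drop[pi, wi, spare] = False
        cube[drop] = np.nan
    # sparse proteins: observed in exactly one replicate everywhere
    for pi in np.where(~survivor)[0]:
        keep = rng.integers(0, R, size=W)
        mask = np.ones((W, R), dtype=bool)
        mask[np.arange(W), keep] = False
        cube[pi][mask] = np.nan

    prot_index = pd.Index(proteins, name="protein")
    flags = pd.DataFrame(index=prot_index)
    flags["contaminant"] = [classes[p] == "contaminant" for p in proteins]
    flags["secreted"] = [classes[p] in ("secreted-dynamic", "flat") for p in proteins]
    flags["ligand"] = [p in ligands or p in decoy_lig for p in proteins]
    flags["sasp"] = False
    flags["serum_residual"] = [classes[p] == "serum-residual" for p in proteins]

    truth.secretome_class = classes
    return SecretomePanel(prot_index, windows, cube, amounts, flags)


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(adata: ad.AnnData, panel: SecretomePanel, truth: GroundTruth,
                  dir_path: str | Path, config: SimConfig | None = None) -> None:
    """Write the simulated study to disk in the pipeline's input formats:
    10X-style matrix directory + cell_meta.tsv, long-format secretome CSV,
    GMT signatures, ligand/receptor/validated-pair CSVs and truth JSON."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_10x_dir(adata, dir_path)
    panel.to_csv(dir_path / "secretome.csv", dir_path / "secretome_flags.csv")

    coll = GeneSetCollection()
    for name, genes in truth.gene_signatures.items():
        role = "phase" if name in ("SPhase", "G2MPhase") else (
            "target" if name == "STAT3_targets" else "signature")
        coll.add(name, genes, role=role)
    write_gmt(coll, dir_path / "signatures.gmt")

    roles = adata.uns.get("sim_roles", {})
    ligands = list(roles.get("ligands", [])) + list(roles.get("decoy_ligands", []))
    receptors = list(roles.get("receptors", [])) + list(roles.get("decoy_receptors", []))
    pd.DataFrame({"gene": ligands}).to_csv(dir_path / "ligands.csv", index=False)
    pd.DataFrame({"gene": receptors}).to_csv(dir_path / "receptors.csv", index=False)

    validated = [(p.ligand, p.receptor) for p in truth.planted_pairs]
    rng = np.random.default_rng((config.seed if config else 0) + 7)
    n_decoy = config.n_decoy_validated if config else 10
    decoys = set()
    if ligands and receptors:
        while len(decoys) < n_decoy:
            pair = (ligands[rng.integers(len(ligands))],
                    receptors[rng.integers(len(receptors))])
            if pair not in validated:
                decoys.add(pair)
    pd.DataFrame(validated + sorted(decoys),
                 columns=["ligand", "receptor"]).to_csv(
        dir_path / "validated_pairs.csv", index=False)
    truth.to_json(dir_path / "truth.json")
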