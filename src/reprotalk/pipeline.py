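"""End-to-end pipeline orchestration.

A single YAML (or in-memory) configuration drives the stages in a fixed
order: simulate-or-read -> secretome -> preprocess -> embed/cluster ->
signatures -> trajectory -> interactions.  Every stage writes its outputs
under the output directory and contributes row counts to a JSON manifest;
the manifest carries the full parameter echo and a content hash of all
outputs, so two runs with the same configuration and seed produce identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import anndata as ad

from . import embedding as emb
from . import interactions as ia
from . import preprocess as pp
from . import secretome as secmod
from . import signatures as sig
from . import simulate as sim
from . import trajectory as tj
from .datasets import (GeneSetCollection, SecretomePanel, read_10x_dir,
                       read_gene_list_csv, read_gmt, read_pair_csv,
                       read_secretome_csv, save_json)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_inputs"]

ALL_STAGES = ("input", "secretome", "preprocess", "embed", "signatures",
              "trajectory", "interactions")


@dataclass
class PipelineConfig:
    """Validated top-level configuration.

    ``input_dir`` reads a fixture directory; if None the synthetic generator
    runs with ``sim``.  ``seed`` propagates into every stage block that does
    not set its own.
    """
    outdir: str = "reprotalk_out"
    seed: int = 0
    input_dir: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    secretome_params: secmod.SecretomeParams = field(default_factory=secmod.SecretomeParams)
    qc: pp.QCParams = field(default_factory=lambda: pp.QCParams(min_genes=150))
    embed: emb.EmbedParams = field(default_factory=emb.EmbedParams)
    markers: sig.MarkerParams = field(default_factory=sig.MarkerParams)
    enrichment: sig.EnrichmentParams = field(default_factory=sig.EnrichmentParams)
    growth: tj.GrowthParams = field(default_factory=tj.GrowthParams)
    transport: tj.TransportParams = field(default_factory=tj.TransportParams)
    interaction: ia.InteractionParams = field(default_factory=ia.InteractionParams)
    endpoints: tuple[str, ...] = ("Matrisome", "LatePluripotency")
    run_layout: bool = False          # FLE is visualisation-only; off by default
    find_markers: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # propagate the global seed into stage blocks left at their default
        for block in (self.sim, self.qc, self.embed, self.enrichment,
                      self.transport, self.interaction):
            if getattr(block, "seed", None) == 0:
                block.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        block_types = {
            "sim": sim.SimConfig, "secretome_params": secmod.SecretomeParams,
            "qc": pp.QCParams, "embed": emb.EmbedParams,
            "markers": sig.MarkerParams, "enrichment": sig.EnrichmentParams,
            "growth": tj.GrowthParams, "transport": tj.TransportParams,
            "interaction": ia.InteractionParams,
        }
        for key, val in raw.items():
            if key in block_types and isinstance(val, dict):
                kwargs[key] = block_types[key](**val)
            elif key in ("stages", "endpoints") and val is not None:
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def read_inputs(dir_path: str | Path):
    """Read a fixture directory into the pipeline's in-memory objects."""
    dir_path = Path(dir_path)
    adata = read_10x_dir(dir_path)
    panel = read_secretome_csv(dir_path / "secretome.csv",
                               dir_path / "secretome_flags.csv")
    gene_sets = read_gmt(dir_path / "signatures.gmt")
    ligands = read_gene_list_csv(dir_path / "ligands.csv")
    receptors = read_gene_list_csv(dir_path / "receptors.csv")
    validated = read_pair_csv(dir_path / "validated_pairs.csv")
    unmatched = [g for g in ligands + receptors if g not in adata.var_names]
    if unmatched:
        log.info("read_inputs: %d annotation symbols not in the matrix "
                 "(e.g. %s)", len(unmatched), unmatched[:3])
    return adata, panel, gene_sets, ligands, receptors, validated


def _hash_update(h, obj) -> None:
    if isinstance(obj, pd.DataFrame):
        h.update(pd.util.hash_pandas_object(obj, index=True).values.tobytes())
    elif isinstance(obj, pd.Series):
        h.update(pd.util.hash_pandas_object(obj, index=True).values.tobytes())
    elif isinstance(obj, np.ndarray):
        if obj.dtype == object or obj.dtype.kind in "US":
            h.update("\n".join(map(str, obj.ravel())).encode())
        else:
            h.update(np.ascontiguousarray(obj).tobytes())
    else:
        h.update(repr(obj).encode())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages end to end; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "counts": {},
                      "params": _echo_params(config)}
    h = hashlib.sha256()

    def stage_done(name: str, **counts) -> None:
        manifest["stages"].append(name)
        manifest["counts"][name] = counts
        log.info("stage %s done: %s", name, counts)

    def fail(name: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # ---- input -------------------------------------------------------
    truth = None
    try:
        if config.input_dir:
            adata, panel, gene_sets, ligands, receptors, validated = \
                read_inputs(config.input_dir)
        else:
            adata, truth = sim.simulate_cells(config.sim)
            panel = sim.simulate_secretome(config.sim, truth)
            gene_sets = GeneSetCollection()
            for name, genes in truth.gene_signatures.items():
                role = "phase" if name.endswith("Phase") else (
                    "target" if name == "STAT3_targets" else "signature")
                gene_sets.add(name, genes, role=role)
            roles = adata.uns["sim_roles"]
            ligands = list(roles["ligands"]) + list(roles["decoy_ligands"])
            receptors = list(roles["receptors"]) + list(roles["decoy_receptors"])
            validated = pd.DataFrame(
                [(p.ligand, p.receptor) for p in truth.planted_pairs],
                columns=["ligand", "receptor"])
    except Exception as exc:
        fail("input", exc)
    stage_done("input", n_cells=adata.n_obs, n_genes=adata.n_vars,
               n_proteins=len(panel.proteins))
    _hash_update(h, adata.obs_names.to_numpy())

    # ---- secretome ---------------------------------------------------
    secreted_panel = panel
    if "secretome" in config.stages:
        try:
            proc = secmod.preprocess_panel(panel, config.secretome_params)
            if "secreted" in proc.flags:
                secreted_panel = proc.subset(
                    proc.proteins[proc.flags["secreted"].to_numpy(dtype=bool)])
            else:
                secreted_panel = proc
            diff = secmod.differential_accumulation(
                secreted_panel, config.secretome_params)
            if len(secreted_panel.proteins) >= 2:
                order, _ = secmod.cluster_profiles(secreted_panel)
                pd.Series(secreted_panel.proteins[order]).to_csv(
                    outdir / "cluster_order.csv", index=False, header=["protein"])
            coords, evr = secmod.pca_panel(secreted_panel)
            long = secreted_panel.to_long()
            long.to_csv(outdir / "retained_panel.csv", index=False)
            diff.to_csv(outdir / "diff_table.csv", index=False)
            coords.to_csv(outdir / "pca_coords.csv")
            _hash_update(h, long); _hash_update(h, diff)
        except Exception as exc:
            fail("secretome", exc)
        stage_done("secretome", n_retained=len(secreted_panel.proteins),
                   n_diff_pass=int(diff["passes"].sum()))

    # ---- preprocess --------------------------------------------------
    if "preprocess" in config.stages:
        try:
            adata = pp.qc_filter(adata, config.qc)
            adata = pp.downsample_per_timepoint(adata, config.qc)
            adata = pp.normalize_and_filter_genes(adata, config.qc)
            if "SPhase" in gene_sets and "G2MPhase" in gene_sets:
                adata = pp.score_cell_cycle(adata, gene_sets, seed=config.qc.seed)
            qc_report = adata.obs[[c for c in ("day", "replicate",
                                               "n_genes_detected",
                                               "mito_fraction", "phase")
                                   if c in adata.obs]]
            qc_report.to_csv(outdir / "qc_report.tsv", sep="\t")
            _hash_update(h, qc_report)
        except Exception as exc:
            fail("preprocess", exc)
        stage_done("preprocess", n_cells=adata.n_obs, n_genes=adata.n_vars)

    # ---- embed -------------------------------------------------------
    clusters = None
    if "embed" in config.stages:
        try:
            adata = emb.embed_cells(adata, config.embed)
            clusters = emb.cluster_cells(adata.obsp["knn"], config.embed)
            adata.obs["cluster"] = clusters
            if config.run_layout:
                pos = emb.force_layout(adata.obsp["knn"], config.embed,
                                       init=adata.obsm["X_embed"][:, :2])
                adata.obsm["X_fle"] = pos
            pd.DataFrame({"barcode": adata.obs_names,
                          "cluster": clusters}).to_csv(
                outdir / "clusters.tsv", sep="\t", index=False)
            _hash_update(h, clusters)
        except Exception as exc:
            fail("embed", exc)
        stage_done("embed", n_clusters=int(len(np.unique(clusters))))

    # ---- signatures --------------------------------------------------
    es: dict[str, np.ndarray] = {}
    if "signatures" in config.stages:
        try:
            for name in gene_sets.names():
                if gene_sets.roles.get(name) in ("signature", "phase"):
                    es[name] = sig.cell_enrichment_score(
                        adata, gene_sets[name], config.enrichment)
                    adata.obs[f"ES_{name}"] = es[name]
            if clusters is not None and "Somatic" in es and "Developmental" in es:
                annot = emb.annotate_clusters(adata, clusters,
                                              es["Somatic"], es["Developmental"])
                annot.to_csv(outdir / "annotation.tsv", sep="\t")
                _hash_update(h, annot)
            if config.find_markers and clusters is not None:
                markers = sig.find_markers(adata, clusters, config.markers)
                markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
                _hash_update(h, markers)
            for name in gene_sets.names():
                if gene_sets.roles.get(name) == "target":
                    act = sig.target_activation(adata, gene_sets[name],
                                                config.enrichment)
                    act.to_csv(outdir / f"activation_{name}.tsv", sep="\t")
                    _hash_update(h, act)
        except Exception as exc:
            fail("signatures", exc)
        stage_done("signatures", n_sets=len(es))

    # ---- trajectory --------------------------------------------------
    trajectories: dict[str, tj.TrajectoryResult] = {}
    if "trajectory" in config.stages:
        try:
            cycle = np.zeros(adata.n_obs)
            if "SPhase" in gene_sets and "G2MPhase" in gene_sets:
                cycle = sig.cell_enrichment_score(
                    adata, gene_sets["SPhase"] + gene_sets["G2MPhase"],
                    config.enrichment)
            apo = es.get("Apoptosis", np.zeros(adata.n_obs))
            growth = tj.compute_growth_rates(cycle, apo, config.growth)
            maps = tj.compute_all_transport_maps(adata, growth, config.transport)
            endpoint_es = {name: es[name] for name in config.endpoints
                           if name in es}
            trajectories = tj.infer_trajectories(
                maps, adata, endpoint_es, config.enrichment.endpoint_threshold)
            rows = []
            for name, res in trajectories.items():
                for bc, prob, memb in zip(res.probabilities.index,
                                          res.probabilities, res.member):
                    rows.append((bc, name, prob, memb))
            tdf = pd.DataFrame(rows, columns=["barcode", "endpoint",
                                              "probability", "member"])
            tdf.to_csv(outdir / "trajectory_probs.tsv", sep="\t", index=False)
            _hash_update(h, tdf)
        except Exception as exc:
            fail("trajectory", exc)
        stage_done("trajectory", n_endpoints=len(trajectories))

    # ---- interactions ------------------------------------------------
    if "interactions" in config.stages:
        try:
            secreted = set(secreted_panel.proteins)
            lig_list = [g for g in ligands
                        if g in secreted and g in adata.var_names]
            pairs, cascade = ia.build_pair_universe(
                lig_list, receptors, adata, validated)
            records = pd.DataFrame()
            top = pd.DataFrame()
            if (len(pairs) and len(trajectories) >= 2):
                names = list(trajectories)
                records = ia.sis_timecourse(
                    adata, trajectories[names[0]].member,
                    trajectories[names[1]].member, pairs, config.interaction)
                top = ia.select_top_pairs(records)
            records.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
            top.to_csv(outdir / "top_pairs.tsv", sep="\t", index=False)
            save_json(cascade, outdir / "cascade_report.json")
            _hash_update(h, records)
        except Exception as exc:
            fail("interactions", exc)
        stage_done("interactions", n_pairs=len(pairs),
                   n_records=len(records), n_top=len(top))

    manifest["hash"] = h.hexdigest()
    save_json(manifest, outdir / "manifest.json")
    return manifest


def _echo_params(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj
    return {f.name: enc(getattr(config, f.name))
            for f in dataclasses.fields(config)}
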