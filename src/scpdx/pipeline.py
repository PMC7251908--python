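"""End-to-end orchestration of the analysis stages.

Stages run in the fixed order validate -> qc -> cluster -> cnv -> signatures
-> lr, each reading the previous stage's in-memory outputs and writing its
own files under the run directory.  A ``manifest.json`` records parameters,
the seed, input file hashes, per-stage status and cell counts; a re-run with
the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import io as scio
from . import ligand_receptor as lr_mod
from . import preprocess, qc, signatures

logger = logging.getLogger(__name__)

STAGES = ["validate", "qc", "cluster", "cnv", "signatures", "lr"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    mtx_dir: str
    out_dir: str
    positions_path: str | None = None  # defaults to gene_positions.tsv in mtx_dir
    markers: dict[str, list[str]] = field(default_factory=dict)
    lr_pairs_path: str | None = None  # defaults to the bundled pair table
    gene_sets: dict[str, list[str]] = field(default_factory=dict)  # e.g. G1S/G2M
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    qc_params: dict = field(default_factory=dict)
    cnv_params: dict = field(default_factory=dict)
    cluster_params: dict = field(default_factory=dict)
    lr_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.mtx_dir).is_dir():
            raise FileNotFoundError(f"mtx_dir {self.mtx_dir} does not exist")
        for path in (self.positions_path, self.lr_pairs_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input {path} does not exist")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")


def validate_inputs(mtx_dir: str | Path) -> list[str]:
    """Consistency checks on a matrix directory; returns non-fatal findings.

    Dimension mismatches between the matrix and barcodes/features are fatal.
    """
    mtx_dir = Path(mtx_dir)
    findings: list[str] = []
    import scipy.io

    matrix = scipy.io.mmread(mtx_dir / "matrix.mtx")
    barcodes = pd.read_csv(mtx_dir / "barcodes.tsv", header=None)[0].astype(str)
    features = pd.read_csv(mtx_dir / "features.tsv", header=None, sep="\t", dtype=str)
    if matrix.shape[0] != len(features):
        raise ValueError(
            f"features count {len(features)} != matrix rows {matrix.shape[0]}"
        )
    if matrix.shape[1] != len(barcodes):
        raise ValueError(
            f"barcodes count {len(barcodes)} != matrix columns {matrix.shape[1]}"
        )
    dup = barcodes[barcodes.duplicated()]
    for b in dup.unique():
        findings.append(f"duplicate barcode {b}")
    if features.shape[1] < 3:
        findings.append("features.tsv has no genome column; species assignment degenerates")
    pos_path = mtx_dir / "gene_positions.tsv"
    if pos_path.exists():
        positions = scio.read_gene_positions(pos_path)
        missing = set(features[0]) - set(positions.index)
        if missing:
            findings.append(f"{len(missing)} genes lack positions (CNV stage will drop them)")
    for finding in findings:
        logger.warning("validate: %s", finding)
    return findings


def _hash_file(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the run directory.

    A stage failure aborts with :class:`StageError`; the manifest and any
    prior stage outputs are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mtx_dir = Path(config.mtx_dir)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "inputs": {
            name: _hash_file(mtx_dir / name)
            for name in ("matrix.mtx", "barcodes.tsv", "features.tsv")
            if (mtx_dir / name).exists()
        },
        "parameters": {
            "qc": config.qc_params,
            "cnv": config.cnv_params,
            "cluster": config.cluster_params,
            "lr": config.lr_params,
        },
    }

    def record(stage: str, status: str, **info) -> None:
        manifest["stages"][stage] = {"status": status, **info}
        scio.write_json(manifest, out / "manifest.json")

    def enabled(stage: str) -> bool:
        on = config.stages.get(stage, True)
        if not on:
            record(stage, "skipped")
        return on

    state: dict = {}
    try:
        if enabled("validate"):
            findings = validate_inputs(mtx_dir)
            record("validate", "completed", findings=findings)
    except StageError:
        raise
    except Exception as exc:
        record("validate", "failed", error=str(exc))
        raise StageError("validate", exc) from exc

    adata = scio.read_cellranger_mtx(mtx_dir)
    state["raw_cells"] = adata.n_obs

    try:
        if enabled("qc"):
            params = qc.QcParams(**config.qc_params)
            species = qc.assign_species(adata, params)
            species.to_csv(out / "species.csv")
            filtered, report = qc.filter_cells(adata, params, species)
            report.per_barcode.to_csv(out / "qc_report.csv")
            scio.write_cellranger_mtx(filtered, out / "filtered")
            adata = filtered
            record(
                "qc",
                "completed",
                cells_in=state["raw_cells"],
                cells_out=adata.n_obs,
                removed_per_rule=report.removed_per_rule.to_dict(),
            )
    except Exception as exc:
        record("qc", "failed", error=str(exc))
        raise StageError("qc", exc) from exc

    norm = labels = None
    try:
        if enabled("cluster"):
            # cluster per species so the two genomes never mix in one embedding
            species = adata.obs.get("species", pd.Series("human", index=adata.obs_names))
            frames = []
            for s in sorted(species.unique()):
                sub = adata[species == s]
                sub = preprocess.gene_prevalence_filter(sub)
                sub_norm = preprocess.tpm_like(sub)
                cluster_kwargs = dict(config.cluster_params)
                n_top = cluster_kwargs.pop("n_top_genes", 300)
                var_genes = preprocess.select_variable_genes(sub_norm, n_top=n_top)
                result = preprocess.reduce_and_cluster(
                    sub_norm, var_genes, seed=config.seed, **cluster_kwargs
                )
                lab = result.labels.map(lambda c: f"{s}:{c}")
                if config.markers:
                    types = preprocess.annotate_clusters(sub_norm, lab, config.markers)
                    cell_type = lab.map(types)
                else:
                    cell_type = lab
                frames.append(pd.DataFrame({"cluster": lab, "cell_type": cell_type}))
            clusters = pd.concat(frames).reindex(adata.obs_names)
            clusters.to_csv(out / "clusters.csv")
            adata.obs[["cluster", "cell_type"]] = clusters
            labels = clusters["cell_type"]
            record("cluster", "completed", n_clusters=int(clusters["cluster"].nunique()))
    except Exception as exc:
        record("cluster", "failed", error=str(exc))
        raise StageError("cluster", exc) from exc

    try:
        if enabled("cnv"):
            pos_path = Path(config.positions_path or mtx_dir / "gene_positions.tsv")
            positions = scio.read_gene_positions(pos_path)
            species = adata.obs.get("species", pd.Series("human", index=adata.obs_names))
            human = adata[species == "human"]
            gene_species = human.var["genome"].astype(str).map(
                lambda g: qc.GENOME_SPECIES.get(g, g)
            )
            human = human[:, (gene_species == "human").to_numpy()]
            human_norm = preprocess.tpm_like(preprocess.gene_prevalence_filter(human))
            caller = cnv_mod.CnvMalignancyCaller(positions=positions, **config.cnv_params)
            calls = caller.fit_predict(human_norm)
            table = pd.DataFrame(
                {
                    "cnv_score": caller.score_,
                    "cnv_correlation": caller.correlation_,
                    "call": calls,
                }
            )
            table.to_csv(out / "cnv_calls.csv")
            caller.cnv_matrix_.to_csv(out / "cnv_matrix.csv")
            state["cnv_calls"] = table
            record("cnv", "completed", calls=calls.value_counts().to_dict())
    except Exception as exc:
        record("cnv", "failed", error=str(exc))
        raise StageError("cnv", exc) from exc

    try:
        if enabled("signatures"):
            norm_all = preprocess.tpm_like(adata)
            g1s = config.gene_sets.get("G1S")
            g2m = config.gene_sets.get("G2M")
            if g1s and g2m:
                cycle = signatures.score_cycle(norm_all, g1s, g2m)
            else:
                cycle = pd.DataFrame(index=adata.obs_names)
            cycle.to_csv(out / "cycle.csv")
            extra = {
                name: genes
                for name, genes in config.gene_sets.items()
                if name not in ("G1S", "G2M")
            }
            if extra:
                scores = signatures.GeneSetScorer(extra).fit_transform(norm_all)
                scores.to_csv(out / "signature_scores.csv")
            record("signatures", "completed", n_sets=len(config.gene_sets))
    except Exception as exc:
        record("signatures", "failed", error=str(exc))
        raise StageError("signatures", exc) from exc

    try:
        if enabled("lr"):
            pairs_path = config.lr_pairs_path or scio.bundled_path("lr_pairs.tsv")
            pairs = scio.read_lr_pairs(pairs_path)
            norm_all = preprocess.tpm_like(adata)
            types = labels if labels is not None else pd.Series("all", index=adata.obs_names)
            network = lr_mod.count_pairs(norm_all, types, pairs, **config.lr_params)
            lr_mod.export_network(network, out)
            record("lr", "completed", n_edges=int(len(network.edges)))
    except Exception as exc:
        record("lr", "failed", error=str(exc))
        raise StageError("lr", exc) from exc

    return out
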