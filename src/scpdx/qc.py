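"""Cell-level quality control and human-mouse demultiplexing.

Filters follow the droplet-QC conventions for PDX data: species is assigned
per barcode from the majority genome of its UMIs, and a cell whose
minority-genome UMI fraction reaches 1% is a cross-species multiplet.  Cells
are then removed when outside 1000-150,000 UMIs or 500-10,000 expressed
genes (count >= 1), above 10% mitochondrial UMI fraction, or with a mean
log-normalized expression of the two housekeeping genes (beta-actin and
GAPDH) below 3 -- the housekeeping check runs on the log2(TPM-like + 1)
scale, i.e. after normalization of the candidate cells.  Tumor-cell clusters
get a stricter gate of more than 2000 expressed genes.

The retained set is the conjunction of the predicates, so filter order does
not affect it; the report attributes each removal to the first failing rule
in the fixed order multiplet, umi, genes, mito, housekeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .preprocess import SCALE_FACTOR, _dense

__all__ = [
    "QcParams",
    "QcReport",
    "assign_species",
    "filter_cells",
    "strict_tumor_filter",
    "cluster_purity_filter",
]

logger = logging.getLogger(__name__)

RULE_ORDER = ["multiplet", "umi_min", "umi_max", "genes_min", "genes_max", "mito", "housekeeping"]

GENOME_SPECIES = {"GRCh38": "human", "hg19": "human", "hg38": "human", "mm10": "mouse", "mm39": "mouse"}


@dataclass
class QcParams:
    umi_max: int = 150_000
    umi_min: int = 1_000
    genes_max: int = 10_000
    genes_min: int = 500
    mito_fraction_max: float = 0.10
    housekeeping_genes: tuple[str, str] = ("ACTB", "GAPDH")
    housekeeping_min_mean: float = 3.0
    cross_species_fraction: float = 0.01
    tumor_cluster_genes_min: int = 2_000
    mito_regex: str = r"^(?:MT-|mt-)"

    def __post_init__(self):
        if not self.umi_min < self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        if not self.genes_min < self.genes_max:
            raise ValueError("genes_min must be < genes_max")
        for name in ("mito_fraction_max", "cross_species_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QcReport:
    per_barcode: pd.DataFrame  # passed (bool), rule (first failing rule or "")
    removed_per_rule: pd.Series
    retained_per_species: pd.Series

    def validate(self) -> None:
        removed = int((~self.per_barcode["passed"]).sum())
        if removed != int(self.removed_per_rule.sum()):
            raise AssertionError("rule attribution does not cover every removed barcode")


def _species_of_genes(var: pd.DataFrame) -> pd.Series:
    genome = var["genome"].astype(str)
    return genome.map(lambda g: GENOME_SPECIES.get(g, g))


def assign_species(adata: ad.AnnData, params: QcParams | None = None) -> pd.Series:
    """Label each barcode human, mouse, or multiplet.

    The majority genome defines the candidate species; the barcode is a
    multiplet iff its minority-genome UMI fraction is at least
    ``cross_species_fraction`` (computed on UMI counts).
    """
    params = params or QcParams()
    if "genome" not in adata.var:
        raise ValueError("features carry no genome tags")
    species = _species_of_genes(adata.var)
    present = [s for s in ("human", "mouse") if (species == s).any()]
    totals = pd.DataFrame(index=adata.obs_names)
    for s in ("human", "mouse"):
        mask = (species == s).to_numpy()
        totals[s] = np.asarray(adata.X[:, mask].sum(axis=1)).ravel()
    grand = totals.sum(axis=1)
    if (grand <= 0).any():
        raise ValueError("every barcode must have at least one count")
    if len(present) < 2:
        logger.warning("matrix contains a single genome (%s); no multiplet detection", present)
        return pd.Series(present[0], index=adata.obs_names, name="species")
    majority = totals.idxmax(axis=1)
    minority_fraction = totals.min(axis=1) / grand
    labels = majority.where(minority_fraction < params.cross_species_fraction, "multiplet")
    return labels.rename("species")


def _housekeeping_mean(adata: ad.AnnData, species: pd.Series, params: QcParams) -> pd.Series:
    """Mean log2(TPM-like + 1) of the cell's own genome's housekeeping genes."""
    names = adata.var.get("gene_name", pd.Series(adata.var_names, index=adata.var_names)).astype(str)
    wanted = {g.upper() for g in params.housekeeping_genes}
    hk_mask = names.str.upper().isin(wanted)
    if not hk_mask.any():
        raise ValueError(
            f"housekeeping genes {params.housekeeping_genes} absent from features"
        )
    gene_species = _species_of_genes(adata.var)
    counts = _dense(adata.X).astype(float)
    depth = counts.sum(axis=1)
    norm = np.log2(1.0 + SCALE_FACTOR * counts / np.maximum(depth, 1)[:, None])
    means = pd.Series(np.nan, index=adata.obs_names)
    for s in ("human", "mouse"):
        cols = np.flatnonzero((hk_mask & (gene_species == s)).to_numpy())
        cells = species[species == s].index
        if len(cells) == 0:
            continue
        if len(cols) == 0:
            raise ValueError(
                f"housekeeping genes {params.housekeeping_genes} absent for genome {s}"
            )
        rows = adata.obs_names.get_indexer(cells)
        means.loc[cells] = norm[np.ix_(rows, cols)].mean(axis=1)
    return means


def filter_cells(
    adata: ad.AnnData,
    params: QcParams | None = None,
    species: pd.Series | None = None,
) -> tuple[ad.AnnData, QcReport]:
    """Apply the QC filters; returns the retained matrix and an itemized report.

    If ``species`` is not supplied it is computed with :func:`assign_species`;
    multiplets are removed first, then the UMI, gene-count, mitochondrial and
    housekeeping rules are evaluated.
    """
    params = params or QcParams()
    if species is None:
        species = assign_species(adata, params)
    species = species.reindex(adata.obs_names)

    counts = _dense(adata.X)
    umis = counts.sum(axis=1)
    n_genes = (counts >= 1).sum(axis=1)
    names = adata.var.get("gene_name", pd.Series(adata.var_names, index=adata.var_names)).astype(str)
    mito_mask = names.str.contains(params.mito_regex, regex=True).to_numpy()
    mito_fraction = counts[:, mito_mask].sum(axis=1) / np.maximum(umis, 1)
    hk_mean = _housekeeping_mean(adata, species, params)

    failures = pd.DataFrame(index=adata.obs_names)
    failures["multiplet"] = (species == "multiplet").to_numpy()
    failures["umi_min"] = umis < params.umi_min
    failures["umi_max"] = umis > params.umi_max
    failures["genes_min"] = n_genes < params.genes_min
    failures["genes_max"] = n_genes > params.genes_max
    failures["mito"] = mito_fraction > params.mito_fraction_max
    failures["housekeeping"] = (hk_mean < params.housekeeping_min_mean).fillna(True).to_numpy()

    failed_any = failures[RULE_ORDER].any(axis=1)
    first_rule = pd.Series("", index=adata.obs_names)
    remaining = failed_any.copy()
    for rule in RULE_ORDER:
        hit = failures[rule] & remaining
        first_rule[hit] = rule
        remaining &= ~hit
    per_barcode = pd.DataFrame({"passed": ~failed_any, "rule": first_rule, "species": species})
    removed_per_rule = first_rule[first_rule != ""].value_counts().reindex(RULE_ORDER, fill_value=0)
    retained = adata[~failed_any.to_numpy()].copy()
    retained.obs["species"] = species[~failed_any].to_numpy()
    report = QcReport(
        per_barcode=per_barcode,
        removed_per_rule=removed_per_rule,
        retained_per_species=per_barcode.loc[per_barcode["passed"], "species"].value_counts(),
    )
    report.validate()
    return retained, report


def strict_tumor_filter(
    adata: ad.AnnData,
    tumor_barcodes,
    params: QcParams | None = None,
) -> pd.Index:
    """Retained barcodes after the strict tumor-cluster gate.

    Tumor barcodes must have strictly more than ``tumor_cluster_genes_min``
    expressed genes; non-tumor barcodes are untouched.
    """
    params = params or QcParams()
    tumor_barcodes = pd.Index(tumor_barcodes)
    missing = tumor_barcodes.difference(adata.obs_names)
    if len(missing):
        raise ValueError(f"tumor barcodes not in matrix, e.g. {missing[:3].tolist()}")
    n_genes = pd.Series(
        np.asarray((adata.X >= 1).sum(axis=1)).ravel(), index=adata.obs_names
    )
    drop = tumor_barcodes[n_genes[tumor_barcodes] <= params.tumor_cluster_genes_min]
    return adata.obs_names.difference(drop, sort=False)


def cluster_purity_filter(
    embedding: np.ndarray,
    labels: pd.Series,
    k: int = 20,
) -> pd.Index:
    """Optional outlier filter: drop cells whose cluster label disagrees with
    the majority label of their k-nearest-neighborhood in the embedding.
    Logged, never applied implicitly."""
    from sklearn.neighbors import NearestNeighbors

    k_eff = min(k + 1, len(labels))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    values = labels.to_numpy()
    keep = []
    for i, row in enumerate(idx):
        neighbor_labels = pd.Series(values[row[1:]])
        majority = neighbor_labels.mode().iloc[0]
        keep.append(values[i] == majority)
    dropped = int(len(keep) - np.sum(keep))
    if dropped:
        logger.info("cluster purity filter dropped %d of %d cells", dropped, len(keep))
    return labels.index[np.asarray(keep)]
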