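"""Reading and writing the pipeline's on-disk formats.

The raw input is a CellRanger-style matrix directory: ``matrix.mtx``
(MatrixMarket coordinate, genes x cells, 1-based), ``barcodes.tsv`` (one
barcode per line) and ``features.tsv`` (gene_id, gene_name, genome).  In
memory everything is an :class:`anndata.AnnData` with cells as ``obs`` and
genes as ``var``; the genome-of-origin tag lives in ``var["genome"]``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "read_cellranger_mtx",
    "write_cellranger_mtx",
    "read_gene_positions",
    "write_gene_positions",
    "read_gmt",
    "write_gmt",
    "read_lr_pairs",
    "read_centroids",
    "bundled_path",
]


def read_cellranger_mtx(directory: str | Path) -> ad.AnnData:
    """Read a CellRanger-dialect matrix directory into an AnnData.

    Expects ``matrix.mtx`` (genes x cells), ``barcodes.tsv`` and
    ``features.tsv`` with columns gene_id, gene_name and optionally genome.
    Returns cells x genes with counts as CSR.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    try:
        matrix = scipy.io.mmread(mtx_path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read matrix at {mtx_path}: {exc}") from exc
    barcodes = pd.read_csv(directory / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
    features = pd.read_csv(directory / "features.tsv", header=None, sep="\t", dtype=str)
    features.columns = ["gene_id", "gene_name", "genome"][: features.shape[1]]
    if "gene_name" not in features:
        features["gene_name"] = features["gene_id"]
    if "genome" not in features:
        features["genome"] = "unknown"
    X = sp.csr_matrix(matrix.T, dtype=np.int64)  # mtx is genes x cells
    if X.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"dimension mismatch in {directory}: matrix is {X.shape[::-1]} "
            f"(genes x cells) but features={len(features)}, barcodes={len(barcodes)}"
        )
    var = features.set_index("gene_id")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return ad.AnnData(X=X, obs=obs, var=var)


def write_cellranger_mtx(adata: ad.AnnData, directory: str | Path) -> None:
    """Write an AnnData of counts as a CellRanger-dialect matrix directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X).T  # genes x cells on disk
    try:
        scipy.io.mmwrite(directory / "matrix.mtx", X, field="integer")
    except OSError as exc:
        raise OSError(f"cannot write matrix under {directory}: {exc}") from exc
    adata.obs_names.to_series().to_csv(directory / "barcodes.tsv", index=False, header=False)
    features = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var.get("gene_name", adata.var_names),
            "genome": adata.var.get("genome", "unknown"),
        }
    )
    features.to_csv(directory / "features.tsv", sep="\t", index=False, header=False)


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    """Read a gene-position table (gene_id, chromosome, start; 1-based)."""
    pos = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "chromosome", "start"}
    if not required.issubset(pos.columns):
        raise ValueError(f"{path}: gene position table needs columns {sorted(required)}")
    return pos.set_index("gene_id")


def write_gene_positions(positions: pd.DataFrame, path: str | Path) -> None:
    positions.reset_index().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            if fields[0] in sets:
                raise ValueError(f"{path}: duplicate gene-set name {fields[0]!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}: empty gene set {fields[0]!r}")
            sets[fields[0]] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, description, *genes]) + "\n")


def read_lr_pairs(path: str | Path) -> pd.DataFrame:
    """Read a ligand-receptor pair table (ligand, receptor[, annotation])."""
    pairs = pd.read_csv(path, sep="\t", dtype=str)
    if not {"ligand", "receptor"}.issubset(pairs.columns):
        raise ValueError(f"{path}: pair table needs 'ligand' and 'receptor' columns")
    if pairs[["ligand", "receptor"]].isna().any().any() or (
        pairs[["ligand", "receptor"]] == ""
    ).any().any():
        raise ValueError(f"{path}: empty ligand/receptor gene names")
    if pairs.duplicated(["ligand", "receptor"]).any():
        dup = pairs[pairs.duplicated(["ligand", "receptor"])].iloc[0]
        raise ValueError(f"{path}: duplicate pair {dup['ligand']}:{dup['receptor']}")
    return pairs.reset_index(drop=True)


def read_centroids(path: str | Path) -> pd.DataFrame:
    """Read subtype centroids: genes x subtypes, blank cells allowed (NaN)."""
    centroids = pd.read_csv(path, sep="\t", index_col=0)
    if centroids.shape[1] == 0:
        raise ValueError(f"{path}: centroid table has no subtype columns")
    return centroids


def bundled_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(resources.files("scpdx.data") / name)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=str)
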