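"""Synthetic mixed-species droplet data with known ground truth.

Emulates a patient-derived-xenograft (PDX) 10x run: human tumor cells carrying
chromosome-arm dosage changes (optionally in several subclones), human and/or
mouse stromal and immune cell types with marker programs, mitochondrial and
housekeeping genes, cross-species ambient contamination and human-mouse
multiplet droplets.  Counts are negative binomial around a per-cell-type
expression program with per-cell depth scaling; copy-number dosage acts
multiplicatively on the NB mean after per-program normalization, so a dosage
of 1.5 raises the expected count of affected genes by exactly 1.5x relative
to a diploid cell of the same program and depth.

Everything is driven by one integer seed; per-stage sub-streams are derived
deterministically so any stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as scio

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "simulate_mixed_pdx",
    "write_fixture",
    "synthetic_bulk_profiles",
]

HOUSEKEEPING_HUMAN = ("ACTB", "GAPDH")
HOUSEKEEPING_MOUSE = ("Actb", "Gapdh")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic PDX droplet run.

    ``cnv_segments`` maps subclone name -> list of
    (chromosome, start_gene_index, end_gene_index, dosage) with gene indices
    0-based half-open *within* the chromosome; segments of one subclone must
    not overlap.  ``marker_genes`` maps cell type -> marker gene names; each
    marker must exist in exactly one genome's gene list.
    """

    n_cells_per_type: Mapping[str, int]
    species_per_type: Mapping[str, str]
    tumor_types: tuple[str, ...] = ("tumor",)
    n_genes_human: int = 3000
    n_genes_mouse: int = 1500
    n_chromosomes: int = 10
    mean_depth: float = 15000.0
    depth_dispersion: float = 0.25
    nb_dispersion: float = 10.0
    mito_fraction_normal: float = 0.03
    mito_fraction_dying: float = 0.25
    dying_cell_rate: float = 0.0
    n_mito_genes: int = 10
    ambient_cross_species_rate: float = 0.005
    multiplet_rate: float = 0.01
    cnv_segments: Mapping[str, Sequence[tuple]] = field(default_factory=dict)
    subclone_fractions: Mapping[str, float] | None = None
    marker_genes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    marker_strength: float = 30.0
    n_cycle_genes: int = 30
    cycle_program_strength: float = 4.0
    cycling_fraction: float = 0.4
    noncycling_fraction: float = 0.4
    lr_pairs_planted: Sequence[tuple[str, str, str, str]] = ()
    lr_strength: float = 20.0
    housekeeping_weight: float = 0.02
    seed: int = 0

    # -- derived gene catalogs -------------------------------------------------
    def gene_names(self, species: str) -> list[str]:
        """Ordered gene names for one genome: housekeeping, mito, generic."""
        if species == "human":
            hk, n = HOUSEKEEPING_HUMAN, self.n_genes_human
            mito = [f"MT-S{i}" for i in range(1, self.n_mito_genes + 1)]
            generic = [f"HGENE{i:05d}" for i in range(n - 2 - self.n_mito_genes)]
        else:
            hk, n = HOUSEKEEPING_MOUSE, self.n_genes_mouse
            mito = [f"mt-S{i}" for i in range(1, self.n_mito_genes + 1)]
            generic = [f"Mgene{i:05d}" for i in range(n - 2 - self.n_mito_genes)]
        return [*hk, *mito, *generic]

    def cycle_gene_sets(self) -> dict[str, list[str]]:
        """Synthetic G1/S and G2/M programs: generic human genes on a stride."""
        generic = [g for g in self.gene_names("human") if g.startswith("HGENE")]
        step = max(1, len(generic) // (2 * self.n_cycle_genes))
        picks = generic[::step]
        g1s = picks[0 : 2 * self.n_cycle_genes : 2][: self.n_cycle_genes]
        g2m = picks[1 : 2 * self.n_cycle_genes : 2][: self.n_cycle_genes]
        return {"G1S": g1s, "G2M": g2m}

    def validate(self) -> None:
        for name, rate in [
            ("mito_fraction_normal", self.mito_fraction_normal),
            ("mito_fraction_dying", self.mito_fraction_dying),
            ("dying_cell_rate", self.dying_cell_rate),
            ("ambient_cross_species_rate", self.ambient_cross_species_rate),
            ("multiplet_rate", self.multiplet_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        genes = {"human": set(self.gene_names("human")), "mouse": set(self.gene_names("mouse"))}
        for ctype, markers in self.marker_genes.items():
            for gene in markers:
                hits = sum(gene in pool for pool in genes.values())
                if hits != 1:
                    raise ValueError(
                        f"marker gene {gene!r} of type {ctype!r} found in {hits} genomes"
                    )
        for ctype, species in self.species_per_type.items():
            if species not in ("human", "mouse"):
                raise ValueError(f"species of {ctype!r} must be human or mouse")
        for ctype in self.n_cells_per_type:
            if ctype not in self.species_per_type:
                raise ValueError(f"no species configured for cell type {ctype!r}")
        genes_per_chrom = self._genes_per_chromosome("human")
        for clone, segments in self.cnv_segments.items():
            seen: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end, dosage in segments:
                chrom = str(chrom)
                if dosage <= 0:
                    raise ValueError(f"subclone {clone!r}: dosage must be > 0, got {dosage}")
                size = genes_per_chrom.get(chrom)
                if size is None:
                    raise ValueError(f"subclone {clone!r}: unknown chromosome {chrom!r}")
                if not (0 <= start < end <= size):
                    raise ValueError(
                        f"subclone {clone!r}: segment [{start}, {end}) out of bounds "
                        f"for chromosome {chrom} with {size} genes"
                    )
                for s0, e0 in seen.get(chrom, []):
                    if start < e0 and s0 < end:
                        raise ValueError(
                            f"subclone {clone!r}: overlapping segments on chromosome {chrom}"
                        )
                seen.setdefault(chrom, []).append((start, end))

    def _genes_per_chromosome(self, species: str) -> dict[str, int]:
        n = self.n_genes_human if species == "human" else self.n_genes_mouse
        base, extra = divmod(n, self.n_chromosomes)
        return {
            str(c + 1): base + (1 if c < extra else 0) for c in range(self.n_chromosomes)
        }


@dataclass
class GroundTruth:
    """Per-barcode truth labels and per-gene dosage profiles per subclone."""

    cells: pd.DataFrame  # index barcode; species, cell_type, malignant, cycle_state, subclone, dying
    dosage: pd.DataFrame  # human genes x subclones, multiplier per gene

    def validate_against(self, adata: ad.AnnData) -> None:
        if not self.cells.index.equals(adata.obs_names):
            raise ValueError("ground truth barcodes do not match matrix barcodes")
        bad = self.cells.query("malignant and species != 'human'")
        if len(bad):
            raise ValueError("tumor labels on non-human cells")


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions: ~2000 cells, 500 human tumor cells in
    two equal subclones whose private arm-level events jointly cover 30% of
    the human genome at dosage 0.5 or 1.5 (each subclone: one whole-chromosome
    gain plus one half-chromosome loss), 500 human stromal/immune cells,
    1000 mouse TME cells."""
    n_cells = {
        "tumor": 500,
        "fibroblast": 170,
        "macrophage": 170,
        "tcell": 160,
        "fibroblast_m": 350,
        "macrophage_m": 350,
        "tcell_m": 150,
        "endothelial_m": 150,
    }
    species = {
        "tumor": "human",
        "fibroblast": "human",
        "macrophage": "human",
        "tcell": "human",
        "fibroblast_m": "mouse",
        "macrophage_m": "mouse",
        "tcell_m": "mouse",
        "endothelial_m": "mouse",
    }
    cfg = SimulationConfig(
        n_cells_per_type=n_cells,
        species_per_type=species,
        seed=seed,
        cnv_segments={
            "clone1": [("1", 0, 300, 1.5), ("3", 0, 150, 0.5)],
            "clone2": [("2", 0, 300, 1.5), ("4", 0, 150, 0.5)],
        },
        subclone_fractions={"clone1": 0.5, "clone2": 0.5},
    )
    # scattered marker programs: 25 genes per type, strided across the genome
    human_generic = [g for g in cfg.gene_names("human") if g.startswith("HGENE")]
    mouse_generic = [g for g in cfg.gene_names("mouse") if g.startswith("Mgene")]
    cycle_genes = set().union(*cfg.cycle_gene_sets().values())
    human_pool = [g for g in human_generic if g not in cycle_genes]
    markers: dict[str, list[str]] = {}
    human_types = [t for t, s in species.items() if s == "human"]
    mouse_types = [t for t, s in species.items() if s == "mouse"]
    for i, ctype in enumerate(human_types):
        markers[ctype] = human_pool[7 + i :: 97][:25]
    for i, ctype in enumerate(mouse_types):
        markers[ctype] = mouse_generic[3 + i :: 53][:25]
    cfg = dataclasses.replace(cfg, marker_genes=markers)
    cfg.validate()
    return cfg


# ----------------------------------------------------------------------------


def _dosage_profiles(config: SimulationConfig) -> pd.DataFrame:
    genes = config.gene_names("human")
    chrom_sizes = config._genes_per_chromosome("human")
    offsets: dict[str, int] = {}
    pos = 0
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = pos
        pos += size
    clones = list(config.cnv_segments) or ["clone1"]
    dosage = pd.DataFrame(1.0, index=genes, columns=clones)
    for clone, segments in config.cnv_segments.items():
        for chrom, start, end, mult in segments:
            lo = offsets[str(chrom)] + start
            hi = offsets[str(chrom)] + end
            dosage.iloc[lo:hi, dosage.columns.get_loc(clone)] = float(mult)
    return dosage


def _base_program(config: SimulationConfig, species: str, rng: np.random.Generator) -> pd.Series:
    """Shared relative-expression backbone of one genome (pre marker/dosage)."""
    genes = config.gene_names(species)
    w = pd.Series(rng.lognormal(mean=0.0, sigma=1.2, size=len(genes)), index=genes)
    hk = HOUSEKEEPING_HUMAN if species == "human" else HOUSEKEEPING_MOUSE
    mito = [g for g in genes if g.startswith(("MT-", "mt-"))]
    generic_sum = w.drop(list(hk) + mito).sum()
    w[list(hk)] = config.housekeeping_weight * generic_sum
    # mito weights set per cell later (normal vs dying fraction); placeholder here
    w[mito] = 0.0
    return w


def _positions_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for species in ("human", "mouse"):
        genes = config.gene_names(species)
        sizes = config._genes_per_chromosome(species)
        idx = 0
        for chrom, size in sizes.items():
            for j in range(size):
                # synthetic coordinates: 10 kb spacing, 1-based
                rows.append((genes[idx], chrom if species == "human" else f"m{chrom}", 1 + j * 10_000))
                idx += 1
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start"]).set_index("gene_id")


def simulate_mixed_pdx(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw one synthetic PDX droplet run.

    Returns the cells x genes count matrix (human then mouse genes, each in
    chromosomal order) and the :class:`GroundTruth`.  Deterministic for a
    fixed config (byte-identical matrices across runs).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["program", "cells", "counts", "ambient", "multiplet"], root.spawn(5)
        )
    }
    genes_h = config.gene_names("human")
    genes_m = config.gene_names("mouse")
    all_genes = genes_h + genes_m
    base = {
        "human": _base_program(config, "human", streams["program"]),
        "mouse": _base_program(config, "mouse", streams["program"]),
    }
    dosage = _dosage_profiles(config)
    clones = list(dosage.columns)
    clone_p = np.array(
        [config.subclone_fractions.get(c, 1 / len(clones)) if config.subclone_fractions else 1 / len(clones) for c in clones]
    )
    clone_p = clone_p / clone_p.sum()
    cycle_sets = config.cycle_gene_sets()

    rng_cells = streams["cells"]
    rng_counts = streams["counts"]

    rows: list[sp.csr_matrix] = []
    meta: list[dict] = []
    gene_index = pd.Index(all_genes)

    for ctype in sorted(config.n_cells_per_type):
        n = int(config.n_cells_per_type[ctype])
        if n == 0:
            continue
        species = config.species_per_type[ctype]
        own_genes = genes_h if species == "human" else genes_m
        w_type = base[species].copy()
        for gene in config.marker_genes.get(ctype, []):
            if gene in w_type.index:
                w_type[gene] *= config.marker_strength
        for ligand, receptor, sender, receiver in config.lr_pairs_planted:
            if ctype == sender and ligand in w_type.index:
                w_type[ligand] *= config.lr_strength
            if ctype == receiver and receptor in w_type.index:
                w_type[receptor] *= config.lr_strength
        is_tumor = ctype in config.tumor_types
        # per-cell latent state
        dying = rng_cells.random(n) < config.dying_cell_rate
        if is_tumor:
            subclone = rng_cells.choice(clones, size=n, p=clone_p)
            u = rng_cells.random(n)
            cycle_state = np.where(
                u < config.cycling_fraction,
                "cycling",
                np.where(u < config.cycling_fraction + config.noncycling_fraction, "non-cycling", "intermediate"),
            )
        else:
            subclone = np.array(["none"] * n)
            cycle_state = np.array(["non-cycling"] * n)

        depth = rng_cells.lognormal(
            mean=np.log(config.mean_depth) - config.depth_dispersion**2 / 2,
            sigma=config.depth_dispersion,
            size=n,
        )
        mito_genes = [g for g in own_genes if g.startswith(("MT-", "mt-"))]
        mf = np.where(dying, config.mito_fraction_dying, config.mito_fraction_normal)

        W = np.tile(w_type[own_genes].to_numpy(float), (n, 1))
        if species == "human":
            cyc = config.cycle_program_strength
            for set_name, set_genes in cycle_sets.items():
                cols = [own_genes.index(g) for g in set_genes]
                up = (cycle_state == "cycling") | (
                    (cycle_state == "intermediate") & (set_name == "G1S")
                )
                factor = np.where(up, cyc, 1.0 / cyc)
                W[:, cols] *= factor[:, None]
        # normalize programs, then set the mitochondrial share of depth
        W /= W.sum(axis=1, keepdims=True)
        mito_cols = [own_genes.index(g) for g in mito_genes]
        if mito_cols:
            W *= (1.0 - mf)[:, None]
            W[:, mito_cols] = (mf / len(mito_cols))[:, None]
        mean_mat = W * depth[:, None]
        if is_tumor:
            d = dosage.loc[own_genes, :].to_numpy(float)
            clone_idx = np.array([clones.index(c) for c in subclone])
            mean_mat = mean_mat * d.T[clone_idx, :]
        # negative binomial: gamma-poisson mixture with shape nb_dispersion
        lam = rng_counts.gamma(shape=config.nb_dispersion, scale=mean_mat / config.nb_dispersion)
        counts_own = rng_counts.poisson(lam)

        block = np.zeros((n, len(all_genes)), dtype=np.int64)
        own_cols = gene_index.get_indexer(own_genes)
        block[:, own_cols] = counts_own
        # ambient cross-species contamination on the other genome
        if config.ambient_cross_species_rate > 0:
            other = "mouse" if species == "human" else "human"
            other_genes = genes_m if species == "human" else genes_h
            p_other = base[other][other_genes].to_numpy(float)
            p_other = p_other / p_other.sum()
            amb_mean = config.ambient_cross_species_rate * depth[:, None] * p_other[None, :]
            amb = streams["ambient"].poisson(amb_mean)
            block[:, gene_index.get_indexer(other_genes)] += amb
        rows.append(block)
        for i in range(n):
            meta.append(
                {
                    "cell_type": ctype,
                    "species": species,
                    "malignant": bool(is_tumor),
                    "cycle_state": cycle_state[i],
                    "subclone": subclone[i],
                    "dying": bool(dying[i]),
                }
            )

    dense = np.vstack(rows) if rows else np.zeros((0, len(all_genes)), dtype=np.int64)
    cells = pd.DataFrame(meta)

    # merge human-mouse doublets into multiplet barcodes
    n_cells_total = dense.shape[0]
    rng_mult = streams["multiplet"]
    human_idx = np.flatnonzero(cells["species"].to_numpy() == "human")
    mouse_idx = np.flatnonzero(cells["species"].to_numpy() == "mouse")
    n_mult = int(round(config.multiplet_rate * n_cells_total))
    n_mult = min(n_mult, len(human_idx), len(mouse_idx))
    if n_mult > 0:
        pick_h = rng_mult.choice(human_idx, size=n_mult, replace=False)
        pick_m = rng_mult.choice(mouse_idx, size=n_mult, replace=False)
        dense[pick_h] += dense[pick_m]
        for h, m in zip(pick_h, pick_m):
            cells.loc[h, "cell_type"] = (
                f"{cells.loc[h, 'cell_type']}+{cells.loc[m, 'cell_type']}"
            )
        cells.loc[pick_h, "species"] = "multiplet"
        cells.loc[pick_h, "malignant"] = False
        keep = np.setdiff1d(np.arange(n_cells_total), pick_m)
        dense = dense[keep]
        cells = cells.iloc[keep].reset_index(drop=True)
    X = sp.csr_matrix(dense)

    barcodes = [f"BC{i:06d}-1" for i in range(X.shape[0])]
    cells.index = pd.Index(barcodes, name="barcode")
    positions = _positions_table(config)
    var = pd.DataFrame(
        {
            "gene_name": all_genes,
            "genome": ["GRCh38"] * len(genes_h) + ["mm10"] * len(genes_m),
        },
        index=pd.Index(all_genes, name="gene_id"),
    )
    adata = ad.AnnData(X=X, obs=cells.copy(), var=var)
    adata.uns["gene_positions"] = positions
    truth = GroundTruth(cells=cells, dosage=dosage)
    truth.validate_against(adata)
    return adata, truth


def write_fixture(adata: ad.AnnData, truth: GroundTruth, directory: str | Path) -> None:
    """Write matrix.mtx/barcodes.tsv/features.tsv + gene_positions.tsv + truth.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scio.write_cellranger_mtx(adata, directory)
    positions = adata.uns.get("gene_positions")
    if positions is not None:
        scio.write_gene_positions(positions, directory / "gene_positions.tsv")
    truth.cells.to_csv(directory / "truth.csv")
    truth.dosage.to_csv(directory / "dosage.csv")


def synthetic_bulk_profiles(
    centroids: pd.DataFrame,
    n_samples: int,
    noise_sd_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Bulk expression profiles drawn as a subtype centroid plus Gaussian noise.

    ``noise_sd_fraction`` scales the noise sd relative to each centroid's own
    spread (standard deviation over its defined genes).  Returns samples x
    genes and the true subtype per sample.
    """
    rng = np.random.default_rng(seed)
    subtypes = list(centroids.columns)
    labels = pd.Series(
        [subtypes[i] for i in rng.integers(0, len(subtypes), size=n_samples)],
        index=[f"S{i:04d}" for i in range(n_samples)],
        name="subtype",
    )
    filled = centroids.apply(lambda col: col.fillna(col.mean()))
    profiles = np.empty((n_samples, centroids.shape[0]))
    for i, lab in enumerate(labels):
        mu = filled[lab].to_numpy(float)
        sd = noise_sd_fraction * float(np.nanstd(centroids[lab].to_numpy(float)))
        profiles[i] = mu + rng.normal(0.0, sd, size=mu.shape)
    return pd.DataFrame(profiles, index=labels.index, columns=centroids.index), labels
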