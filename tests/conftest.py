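"""Shared fixtures: synthetic datasets generated once per session."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from scpdx import preprocess, simulate


@pytest.fixture(scope="session")
def default_run():
    """The default study conditions (~2000 mixed-species cells, two tumor
    subclones, 30% of the human genome at dosage 0.5/1.5)."""
    config = simulate.default_config(seed=0)
    adata, truth = simulate.simulate_mixed_pdx(config)
    return config, adata, truth


@pytest.fixture(scope="session")
def human_norm(default_run):
    """Log-normalized human compartment of the default run (human genes only)."""
    config, adata, truth = default_run
    human = adata[(truth.cells["species"] == "human").to_numpy()]
    human = human[:, (human.var["genome"] == "GRCh38").to_numpy()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = preprocess.tpm_like(preprocess.gene_prevalence_filter(human))
    return norm


@pytest.fixture(scope="session")
def clean_two_type_run():
    """Two well-separated human populations: disjoint marker programs, no
    CNV, no cycle modulation, no contamination or multiplets."""
    base = simulate.default_config(seed=0)
    config = dataclasses.replace(
        base,
        n_cells_per_type={"fibroblast": 150, "tcell": 150},
        species_per_type={"fibroblast": "human", "tcell": "human"},
        tumor_types=(),
        cnv_segments={},
        subclone_fractions=None,
        cycle_program_strength=1.0,
        multiplet_rate=0.0,
        ambient_cross_species_rate=0.0,
        marker_genes={
            k: v for k, v in base.marker_genes.items() if k in ("fibroblast", "tcell")
        },
    )
    adata, truth = simulate.simulate_mixed_pdx(config)
    return config, adata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_norm_frame():
    """A small deterministic cells x genes expression frame."""
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(40)]
    cells = [f"C{i:02d}" for i in range(12)]
    return pd.DataFrame(
        rng.gamma(2.0, 2.0, size=(len(cells), len(genes))), index=cells, columns=genes
    )
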