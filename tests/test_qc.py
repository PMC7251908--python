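"""QC rules: species demultiplexing, cell filters, planted-violation audit."""

from __future__ import annotations

import dataclasses
import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scpdx import qc, simulate


def build_matrix(cells: dict[str, dict[str, int]], n_generic: int = 10_046) -> ad.AnnData:
    """Dense toy matrix with named human housekeeping/mito genes, a generic
    human gene pool and a few mouse genes.  ``cells`` maps barcode ->
    {gene: count} where 'generic:K:V' spreads count V over the first K
    generic genes."""
    genes = (
        ["ACTB", "GAPDH", "MT-1", "MT-2"]
        + [f"HG{i:05d}" for i in range(n_generic)]
        + ["Actb", "Gapdh", "Mg1", "Mg2", "Mg3"]
    )
    genome = ["GRCh38"] * (4 + n_generic) + ["mm10"] * 5
    X = np.zeros((len(cells), len(genes)), dtype=np.int64)
    index = {g: i for i, g in enumerate(genes)}
    for row, (_, spec) in enumerate(cells.items()):
        for key, value in spec.items():
            if key.startswith("generic:"):
                _, k, v = key.split(":")
                X[row, index["HG00000"] : index["HG00000"] + int(k)] = int(v)
            else:
                X[row, index[key]] = value
    return ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=pd.Index(cells.keys(), name="barcode")),
        var=pd.DataFrame({"gene_name": genes, "genome": genome}, index=genes),
    )


GOOD = {"ACTB": 200, "GAPDH": 200, "MT-1": 40, "generic:1500:3": 0}


@pytest.fixture(scope="module")
def audit_matrix():
    """Exactly one planted violation per QC rule, plus boundary passes."""
    cells = {
        "ok1": dict(GOOD),
        "ok2": dict(GOOD),
        "ok3": dict(GOOD),
        # umi_min: 999 total fails, 1000 passes (strict < 1000 removal rule)
        "umi_low": {"ACTB": 200, "GAPDH": 200, "generic:599:1": 0},
        "umi_boundary_pass": {"ACTB": 200, "GAPDH": 201, "generic:599:1": 0},
        # umi_max: > 150000 fails
        "umi_high": {"ACTB": 75000, "GAPDH": 74000, "generic:1001:1": 0},
        # genes_min: 499 expressed genes fails (< 500)
        "genes_low": {"ACTB": 300, "GAPDH": 300, "generic:497:2": 0},
        # genes_max: 10003 expressed genes fails (> 10000)
        "genes_high": {"ACTB": 3000, "GAPDH": 3000, "generic:10001:1": 0},
        # mito: 150/1350 = 11.1% > 10%
        "mito_high": {"ACTB": 300, "GAPDH": 300, "MT-1": 150, "generic:600:1": 0},
        # housekeeping: no ACTB/GAPDH at all
        "hk_low": {"generic:700:2": 0},
        # multiplet: 30/2030 = 1.48% mouse
        "multiplet": {"ACTB": 1000, "GAPDH": 1000, "Mg1": 30},
        # species boundary: exactly 1% minority -> multiplet ("at least 1%")
        "species_boundary_fail": {"ACTB": 495, "GAPDH": 490, "generic:500:1": 0, "Mg1": 15},
        # just under 1% minority -> clean human cell
        "species_boundary_pass": {"ACTB": 496, "GAPDH": 496, "generic:500:1": 0, "Mg1": 14},
    }
    return build_matrix(cells)


def naive_qc_oracle(adata: ad.AnnData, params: qc.QcParams) -> dict[str, str]:
    """Brute-force per-cell re-evaluation of every QC predicate in a plain
    loop, independent of the vectorized implementation."""
    X = np.asarray(adata.X.todense(), dtype=float)
    names = adata.var["gene_name"].tolist()
    genome = adata.var["genome"].tolist()
    verdicts = {}
    for row, barcode in enumerate(adata.obs_names):
        counts = X[row]
        human = sum(c for c, g in zip(counts, genome) if g == "GRCh38")
        mouse = sum(c for c, g in zip(counts, genome) if g == "mm10")
        minority = min(human, mouse) / (human + mouse)
        if minority >= params.cross_species_fraction:
            verdicts[barcode] = "multiplet"
            continue
        species_tag = "GRCh38" if human >= mouse else "mm10"
        total = counts.sum()
        if total < params.umi_min:
            verdicts[barcode] = "umi_min"
            continue
        if total > params.umi_max:
            verdicts[barcode] = "umi_max"
            continue
        n_genes = int((counts >= 1).sum())
        if n_genes < params.genes_min:
            verdicts[barcode] = "genes_min"
            continue
        if n_genes > params.genes_max:
            verdicts[barcode] = "genes_max"
            continue
        mito = sum(
            c for c, n in zip(counts, names) if n.startswith("MT-") or n.startswith("mt-")
        )
        if mito / total > params.mito_fraction_max:
            verdicts[barcode] = "mito"
            continue
        hk = [
            math.log2(1.0 + 1e6 * c / total)
            for c, n, g in zip(counts, names, genome)
            if n.upper() in {h.upper() for h in params.housekeeping_genes} and g == species_tag
        ]
        if sum(hk) / len(hk) < params.housekeeping_min_mean:
            verdicts[barcode] = "housekeeping"
            continue
        verdicts[barcode] = ""
    return verdicts


class TestAssignSpecies:
    @pytest.mark.parametrize(
        "human_umis, mouse_umis, expected",
        [
            (1000, 5, "human"),  # 0.5% minority
            (1000, 20, "multiplet"),  # ~2% minority
            (0, 500, "mouse"),  # pure cell
            (990, 10, "multiplet"),  # exactly 1% -> at least 1% rule
        ],
    )
    def test_threshold_rule(self, human_umis, mouse_umis, expected):
        adata = build_matrix(
            {"bc": {"ACTB": human_umis, "Mg1": mouse_umis}}, n_generic=1
        )
        assert qc.assign_species(adata).loc["bc"] == expected

    def test_single_genome_matrix_labels_everything_that_genome(self):
        adata = build_matrix({"bc1": {"ACTB": 10}, "bc2": {"GAPDH": 7}}, n_generic=1)
        adata = adata[:, (adata.var["genome"] == "GRCh38").to_numpy()].copy()
        labels = qc.assign_species(adata)
        assert (labels == "human").all()

    def test_clean_synthetic_data_recovers_species_exactly(self, clean_two_type_run):
        _, adata, truth = clean_two_type_run
        labels = qc.assign_species(adata)
        assert (labels == truth.cells["species"]).all()


class TestFilterCells:
    def test_planted_violation_counts_match_audit(self, audit_matrix):
        params = qc.QcParams()
        filtered, report = qc.filter_cells(audit_matrix, params)
        planted = {
            "multiplet": 2,
            "umi_min": 1,
            "umi_max": 1,
            "genes_min": 1,
            "genes_max": 1,
            "mito": 1,
            "housekeeping": 1,
        }
        assert report.removed_per_rule[report.removed_per_rule > 0].to_dict() == planted
        assert filtered.n_obs == audit_matrix.n_obs - sum(planted.values())
        # boundary cells pass
        passed = set(filtered.obs_names)
        assert {"umi_boundary_pass", "species_boundary_pass"} <= passed
        assert "species_boundary_fail" not in passed

    def test_rule_attribution_matches_naive_loop_oracle(self, audit_matrix):
        params = qc.QcParams()
        _, report = qc.filter_cells(audit_matrix, params)
        oracle = naive_qc_oracle(audit_matrix, params)
        got = report.per_barcode["rule"].to_dict()
        assert got == oracle

    def test_retained_set_is_conjunction_of_predicates(self, audit_matrix):
        """Order insensitivity: the retained set equals the cells passing
        every predicate, regardless of attribution order."""
        params = qc.QcParams()
        filtered, _ = qc.filter_cells(audit_matrix, params)
        oracle = naive_qc_oracle(audit_matrix, params)
        expected = {bc for bc, rule in oracle.items() if rule == ""}
        assert set(filtered.obs_names) == expected

    def test_report_is_internally_consistent(self, audit_matrix):
        _, report = qc.filter_cells(audit_matrix)
        report.validate()
        assert report.per_barcode.shape[0] == audit_matrix.n_obs
        assert int(report.retained_per_species.sum()) == int(report.per_barcode["passed"].sum())

    def test_missing_housekeeping_genes_is_hard_error(self):
        adata = build_matrix({"bc": {"generic:600:2": 0}}, n_generic=600)
        adata = adata[:, ~adata.var_names.isin(["ACTB", "GAPDH"])].copy()
        with pytest.raises(ValueError, match="ACTB"):
            qc.filter_cells(adata)

    def test_no_multiplets_labeled_below_one_percent_contamination(self, default_run):
        """Default ambient rate (0.5%) stays under the 1% rule for singlets."""
        _, adata, truth = default_run
        labels = qc.assign_species(adata)
        singlets = truth.cells["species"] != "multiplet"
        assert (labels[singlets.to_numpy()] != "multiplet").mean() > 0.99


class TestStrictTumorFilter:
    def make(self, n_genes_expressed: int) -> ad.AnnData:
        return build_matrix(
            {
                "tumor_cell": {"ACTB": 50, "GAPDH": 50, f"generic:{n_genes_expressed - 2}:1": 0},
                "stromal_cell": {"ACTB": 10, "GAPDH": 10, "generic:598:1": 0},
            },
            n_generic=10_046,
        )

    def test_boundary_is_strictly_greater_than(self):
        params = qc.QcParams()
        kept_2001 = qc.strict_tumor_filter(self.make(2001), ["tumor_cell"], params)
        assert "tumor_cell" in kept_2001
        kept_2000 = qc.strict_tumor_filter(self.make(2000), ["tumor_cell"], params)
        assert "tumor_cell" not in kept_2000

    def test_non_tumor_cells_untouched(self):
        kept = qc.strict_tumor_filter(self.make(2000), ["tumor_cell"])
        assert "stromal_cell" in kept

    def test_unknown_tumor_barcode_rejected(self):
        with pytest.raises(ValueError, match="not in matrix"):
            qc.strict_tumor_filter(self.make(2001), ["nope"])


def test_params_validation():
    with pytest.raises(ValueError, match="umi_min"):
        qc.QcParams(umi_min=200_000)
    with pytest.raises(ValueError, match="mito_fraction_max"):
        qc.QcParams(mito_fraction_max=1.5)
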