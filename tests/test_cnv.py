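"""Inferred-CNV chain: preparation, windowing oracle, scoring, calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpdx import cnv


def positions_for(genes, chromosomes):
    return pd.DataFrame(
        {"chromosome": chromosomes, "start": range(1, len(genes) + 1)},
        index=pd.Index(genes, name="gene_id"),
    )


def naive_moving_average(values: np.ndarray, chrom: list[str], w: int) -> np.ndarray:
    """Independent brute-force oracle: per cell, per gene, average the
    centered window of up to w genes within the same chromosome."""
    n_cells, n_genes = values.shape
    out = np.zeros_like(values)
    half_left = (w - 1) // 2
    for i in range(n_genes):
        lo, hi = i - half_left, i - half_left + w
        window = [
            j for j in range(max(lo, 0), min(hi, n_genes)) if chrom[j] == chrom[i]
        ]
        # clip to the contiguous chromosome block around i
        window = [j for j in window if all(chrom[k] == chrom[i] for k in range(min(j, i), max(j, i) + 1))]
        for c in range(n_cells):
            out[c, i] = np.mean([values[c, j] for j in window])
    out = out - out.mean(axis=1, keepdims=True)
    return out


class TestPrepareExpression:
    def test_low_expression_and_zero_variance_rules(self):
        genes = ["low", "const", "ok"]
        X = pd.DataFrame(
            {"low": [0.1, 0.1, 0.1], "const": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]},
            index=["c1", "c2", "c3"],
        )
        pos = positions_for(genes, ["1", "1", "1"])
        params = cnv.CnvParams(window_genes=1)
        prepared, chrom = cnv.prepare_expression(X, pos, params)
        assert "low" not in prepared.columns  # mean 0.1 < 0.2 discarded
        assert (prepared["const"] == 0).all()  # zero-variance -> all-zero column
        assert prepared["ok"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_values_clipped_to_three(self):
        X = pd.DataFrame({"g": [1.0] * 20 + [100.0]})
        pos = positions_for(["g"], ["1"])
        prepared, _ = cnv.prepare_expression(X, pos, cnv.CnvParams(window_genes=1))
        assert prepared["g"].max() == pytest.approx(3.0)
        assert prepared["g"].abs().max() <= 3.0

    def test_genes_ordered_by_karyotype_chromosome_then_start(self):
        genes = ["gX", "g2", "g10", "g1b", "g1a"]
        X = pd.DataFrame(np.ones((3, 5)) + np.eye(3, 5), columns=genes)
        pos = pd.DataFrame(
            {
                "chromosome": ["X", "2", "10", "1", "1"],
                "start": [5, 7, 1, 20, 10],
            },
            index=pd.Index(genes, name="gene_id"),
        )
        prepared, chrom = cnv.prepare_expression(X, pos, cnv.CnvParams(window_genes=1))
        assert list(prepared.columns) == ["g1a", "g1b", "g2", "g10", "gX"]
        assert list(chrom) == ["1", "1", "2", "10", "X"]

    def test_unpositioned_genes_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        pos = positions_for(["a"], ["1"])
        with pytest.warns(UserWarning, match="without a position"):
            prepared, _ = cnv.prepare_expression(X, pos, cnv.CnvParams(window_genes=1))
        assert list(prepared.columns) == ["a"]

    def test_error_when_every_chromosome_smaller_than_window(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(2, 1, (5, 4)) + 2, columns=list("abcd"))
        pos = positions_for(list("abcd"), ["1", "1", "2", "2"])
        with pytest.raises(ValueError, match="window_genes"):
            cnv.prepare_expression(X, pos, cnv.CnvParams(window_genes=100))


class TestMovingAverage:
    def test_all_zero_input_stays_zero(self):
        X = pd.DataFrame(np.zeros((3, 10)))
        chrom = pd.Series(["1"] * 10, index=X.columns)
        out = cnv.moving_average(X, chrom, cnv.CnvParams(window_genes=3))
        assert (out.to_numpy() == 0).all()

    def test_window_one_is_recentered_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 8)))
        chrom = pd.Series(["1"] * 8, index=X.columns)
        out = cnv.moving_average(X, chrom, cnv.CnvParams(window_genes=1))
        expected = X.sub(X.mean(axis=1), axis=0)
        np.testing.assert_allclose(out.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_matches_naive_loop_on_toy_chromosome(self, rng):
        """10-gene chromosome, window 3, against the brute-force oracle."""
        X = pd.DataFrame(rng.normal(size=(5, 10)))
        chrom = pd.Series(["1"] * 10, index=X.columns)
        out = cnv.moving_average(X, chrom, cnv.CnvParams(window_genes=3))
        expected = naive_moving_average(X.to_numpy(), ["1"] * 10, 3)
        assert np.abs(out.to_numpy() - expected).max() < 1e-12

    @settings(deadline=None, max_examples=25)
    @given(
        n_genes=st.integers(5, 30),
        w=st.integers(1, 12),
        split=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    def test_matches_naive_loop_across_chromosome_layouts(self, n_genes, w, split, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(3, n_genes)))
        bounds = sorted(rng.choice(np.arange(1, n_genes), size=min(split, n_genes - 1), replace=False))
        chrom_names = []
        prev = 0
        for k, b in enumerate([*bounds, n_genes]):
            chrom_names += [str(k + 1)] * (b - prev)
            prev = b
        chrom = pd.Series(chrom_names, index=X.columns)
        out = cnv.moving_average(X, chrom, cnv.CnvParams(window_genes=w))
        expected = naive_moving_average(X.to_numpy(), chrom_names, w)
        assert np.abs(out.to_numpy() - expected).max() < 1e-12

    def test_per_cell_mean_zero_after_recentering(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 20)))
        chrom = pd.Series(["1"] * 12 + ["2"] * 8, index=X.columns)
        out = cnv.moving_average(X, chrom, cnv.CnvParams(window_genes=5))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_windows_never_mix_chromosomes(self, rng):
        """Permuting chromosome block order permutes output blocks identically."""
        X = pd.DataFrame(rng.normal(size=(4, 12)), columns=[f"g{i}" for i in range(12)])
        chrom = pd.Series(["1"] * 6 + ["2"] * 6, index=X.columns)
        out = cnv.moving_average(X, chrom, cnv.CnvParams(window_genes=4))
        # swap the blocks and recompute
        swapped_cols = list(X.columns[6:]) + list(X.columns[:6])
        X2 = X[swapped_cols]
        chrom2 = chrom[swapped_cols]
        out2 = cnv.moving_average(X2, chrom2, cnv.CnvParams(window_genes=4))
        np.testing.assert_allclose(
            out[X.columns].to_numpy(), out2[X.columns].to_numpy(), atol=1e-12
        )


class TestCnvScore:
    def test_mean_of_squares_example(self):
        assert cnv.cnv_score(np.array([0.1, -0.1, 0.2])) == pytest.approx(0.02)

    def test_zeros(self):
        assert cnv.cnv_score(np.zeros(5)) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(c=st.floats(-10, 10, allow_nan=False), seed=st.integers(0, 1000))
    def test_scaling_homogeneity(self, c, seed):
        row = np.random.default_rng(seed).normal(size=20)
        assert cnv.cnv_score(c * row) == pytest.approx(c**2 * cnv.cnv_score(row), rel=1e-9, abs=1e-12)


def make_result(matrix: pd.DataFrame) -> cnv.CnvResult:
    chrom = pd.Series(["1"] * matrix.shape[1], index=matrix.columns)
    return cnv.malignancy_call(matrix, chrom)


class TestMalignancyCall:
    @pytest.mark.parametrize(
        "score, corr, expected",
        [
            (0.03, 0.5, "tumor"),  # both above
            (0.01, 0.1, "non-tumor"),  # both below
            (0.03, 0.1, "undetermined"),  # discordant high/low
            (0.01, 0.5, "undetermined"),  # discordant low/high
            (0.02, 0.5, "undetermined"),  # score exactly at cutoff
            (0.03, 0.2, "undetermined"),  # correlation exactly at cutoff
            (0.02, 0.2, "undetermined"),  # both exactly at cutoffs
            (0.03, float("nan"), "undetermined"),  # undefined correlation
            (0.03, -0.5, "undetermined"),  # anti-correlated but high score
            (0.0, 0.0, "non-tumor"),  # degenerate zero cell: both below
        ],
    )
    def test_two_cutoff_rule_table(self, score, corr, expected):
        """Exhaustive strict-inequality rule table, including boundaries."""
        call = cnv.call_from_cutoffs(
            pd.Series([score], index=["c"]), pd.Series([corr], index=["c"])
        )
        assert call["c"] == expected

    def test_reference_is_mean_of_top_score_cells(self, rng):
        matrix = pd.DataFrame(rng.normal(0, 0.05, size=(40, 30)))
        matrix.iloc[0] += 2.0  # single dominant cell: top 5% of 40 = 2 cells
        result = make_result(matrix)
        top2 = result.score.sort_values(ascending=False).index[:2]
        np.testing.assert_allclose(
            result.reference_profile.to_numpy(),
            matrix.loc[top2].mean(axis=0).to_numpy(),
            atol=1e-12,
        )

    def test_constant_reference_makes_all_calls_undetermined(self):
        matrix = pd.DataFrame(np.zeros((10, 8)))
        result = make_result(matrix)
        assert (result.call == "undetermined").all()
        assert result.correlation.isna().all()


class TestRecalibrate:
    def test_non_tumor_profiles_average_zero_after_recalibration(self, rng):
        tumor = rng.normal(0.5, 0.3, size=(6, 20))
        normal = rng.normal(0.0, 0.05, size=(30, 20))
        matrix = pd.DataFrame(np.vstack([tumor, normal]))
        first = make_result(matrix)
        non_tumor = first.call.index[first.call == "non-tumor"]
        assert len(non_tumor) > 0
        recal = cnv.recalibrate(first)
        assert recal.calibrated
        np.testing.assert_allclose(
            recal.matrix.loc[non_tumor].mean(axis=0), 0.0, atol=1e-10
        )

    def test_identical_cells_recalibrate_to_zero(self):
        matrix = pd.DataFrame(np.tile(np.linspace(-1, 1, 10), (12, 1)))
        first = make_result(matrix)
        if (first.call == "non-tumor").any():
            recal = cnv.recalibrate(first)
            assert np.allclose(recal.matrix.to_numpy(), 0.0)

    def test_no_non_tumor_cells_skips_with_warning(self, rng):
        matrix = pd.DataFrame(rng.normal(1, 0.1, size=(10, 12)))
        first = make_result(matrix)
        first.call[:] = "tumor"
        with pytest.warns(UserWarning, match="uncalibrated"):
            recal = cnv.recalibrate(first)
        assert not recal.calibrated


class TestCallerOnSyntheticTruth:
    def test_planted_gain_positive_after_recalibration(self, default_run, human_norm):
        """Recalibrated tumor-cell mean over a planted gain is positive;
        neutral segments sit near zero (sign check against planted truth)."""
        _, adata, truth = default_run
        caller = cnv.CnvMalignancyCaller(positions=adata.uns["gene_positions"]).fit(human_norm)
        assert caller.result_.calibrated
        cells = truth.cells.loc[caller.cnv_matrix_.index]
        clone1 = cells.index[(cells["subclone"] == "clone1").to_numpy()]
        genes = caller.cnv_matrix_.columns
        gained = [g for g in genes if truth.dosage.loc[g, "clone1"] == 1.5]
        neutral = [
            g for g in genes if (truth.dosage.loc[g] == 1.0).all()
        ]
        gain_mean = caller.cnv_matrix_.loc[clone1, gained].mean().mean()
        neutral_mean = caller.cnv_matrix_.loc[clone1, neutral].mean().mean()
        assert gain_mean > 0.1
        assert abs(neutral_mean) < 0.05

    def test_estimator_params_roundtrip(self):
        caller = cnv.CnvMalignancyCaller(window_genes=50, score_cutoff=0.03)
        params = caller.get_params()
        assert params["window_genes"] == 50
        clone = cnv.CnvMalignancyCaller(**params)
        assert clone.get_params() == params
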