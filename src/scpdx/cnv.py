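"""Expression-derived copy-number inference and malignancy calling.

The procedure estimates large-scale chromosomal dosage from smoothed,
position-ordered expression: low-expression genes (mean log-normalized value
< 0.2) are discarded, each remaining gene is standardized across cells
(center + unit variance; one standardization, since centering is idempotent)
and clipped to [-3, 3] so single outlier genes cannot distort the smoothing,
genes are sorted by (chromosome, start) in karyotype order, and a 100-gene
moving average is taken along each chromosome (truncated at chromosome ends,
never spanning two chromosomes, step 1).  Each cell's smoothed profile is
then re-centered to mean zero.

Malignancy is called from two per-cell summaries:

* CNV score — mean of squared inferred-CNV values (overall dosage distortion);
* CNV correlation — Pearson r of the cell's profile against a putative-
  malignant reference, the per-gene mean profile of the cells in the top 5%
  of CNV scores.

Cells with score > 0.02 and correlation > 0.2 are tumor, cells with both
below the cutoffs are non-tumor, everything else (including values exactly
at a cutoff) is undetermined.  A single recalibration pass then subtracts
the mean profile of the non-tumor cells (the diploid reference) and recomputes
scores, correlations and calls once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .preprocess import _dense

__all__ = [
    "CnvParams",
    "CnvResult",
    "CnvMalignancyCaller",
    "prepare_expression",
    "moving_average",
    "cnv_score",
    "malignancy_call",
    "recalibrate",
    "karyotype_order",
]

logger = logging.getLogger(__name__)

TUMOR, NON_TUMOR, UNDETERMINED = "tumor", "non-tumor", "undetermined"


@dataclass
class CnvParams:
    low_expression_mean_min: float = 0.2
    clip_abs: float = 3.0
    window_genes: int = 100
    top_score_fraction: float = 0.05
    score_cutoff: float = 0.02
    correlation_cutoff: float = 0.2
    chromosome_order: list[str] | None = None

    def __post_init__(self):
        if self.window_genes < 1:
            raise ValueError("window_genes must be >= 1")
        if not 0 < self.top_score_fraction <= 1:
            raise ValueError("top_score_fraction must be in (0, 1]")
        if self.score_cutoff <= 0 or self.correlation_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class CnvResult:
    matrix: pd.DataFrame  # cells x ordered genes, inferred CNV
    chromosomes: pd.Series  # per ordered gene
    score: pd.Series
    correlation: pd.Series
    call: pd.Series
    reference_profile: pd.Series
    calibrated: bool = False
    params: CnvParams = field(default_factory=CnvParams)


def karyotype_order(chromosomes) -> list[str]:
    """Sort chromosome names in karyotype order: 1..22, X, Y, then others."""

    def key(name: str):
        stripped = str(name)
        for prefix in ("chr", "m"):
            if stripped.startswith(prefix):
                stripped = stripped[len(prefix):]
        if stripped.isdigit():
            return (0, int(stripped), "")
        if stripped in ("X", "Y"):
            return (1, {"X": 0, "Y": 1}[stripped], "")
        return (2, 0, str(name))

    return sorted(pd.unique(pd.Series(list(chromosomes)).astype(str)), key=key)


def prepare_expression(
    norm: ad.AnnData | pd.DataFrame,
    positions: pd.DataFrame,
    params: CnvParams | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter, standardize, clip and order the expression matrix.

    Returns (cells x ordered genes matrix, chromosome per ordered gene).
    Genes without a position are dropped with a warning; genes whose mean
    expression is below the low-expression cutoff are discarded; zero-variance
    genes become all-zero columns; values are clipped to +-clip_abs.
    """
    params = params or CnvParams()
    if isinstance(norm, ad.AnnData):
        X = pd.DataFrame(_dense(norm.X), index=norm.obs_names, columns=norm.var_names)
    else:
        X = norm.astype(float)
    positioned = X.columns.intersection(positions.index)
    dropped = len(X.columns) - len(positioned)
    if dropped:
        warnings.warn(f"{dropped} genes without a position dropped from CNV inference")
    X = X[positioned]
    X = X.loc[:, X.mean(axis=0) >= params.low_expression_mean_min]
    if X.shape[1] == 0:
        raise ValueError("no genes survive the low-expression filter")
    sd = X.std(axis=0, ddof=0)
    Z = (X - X.mean(axis=0)).div(sd.replace(0.0, np.inf), axis=1)
    Z = Z.clip(-params.clip_abs, params.clip_abs)
    chrom = positions.loc[Z.columns, "chromosome"].astype(str)
    order = params.chromosome_order or karyotype_order(chrom)
    chrom_rank = {c: i for i, c in enumerate(order)}
    gene_order = sorted(
        Z.columns,
        key=lambda g: (chrom_rank.get(chrom[g], len(chrom_rank)), positions.loc[g, "start"], g),
    )
    Z = Z[gene_order]
    chrom = chrom[gene_order]
    sizes = chrom.value_counts()
    if (sizes < params.window_genes).all():
        raise ValueError(
            f"every chromosome has fewer than window_genes={params.window_genes} genes"
        )
    return Z, chrom


def moving_average(
    prepared: pd.DataFrame,
    chromosomes: pd.Series,
    params: CnvParams | None = None,
) -> pd.DataFrame:
    """Per-chromosome centered moving average over ``window_genes`` genes.

    The window around gene i covers the ``window_genes`` consecutive genes
    centered at i, truncated at chromosome boundaries (edge windows are
    shorter; windows never span chromosomes).  After smoothing, each cell's
    profile is re-centered to mean zero.
    """
    params = params or CnvParams()
    w = params.window_genes
    half_left = (w - 1) // 2
    half_right = w // 2
    out = np.empty_like(prepared.to_numpy(float))
    values = prepared.to_numpy(float)
    col = 0
    for chrom in chromosomes.unique():
        n = int((chromosomes == chrom).sum())
        block = values[:, col : col + n]
        cs = np.zeros((block.shape[0], n + 1))
        np.cumsum(block, axis=1, out=cs[:, 1:])
        lo = np.maximum(np.arange(n) - half_left, 0)
        hi = np.minimum(np.arange(n) + half_right + 1, n)
        out[:, col : col + n] = (cs[:, hi] - cs[:, lo]) / (hi - lo)
        col += n
    out -= out.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=prepared.index, columns=prepared.columns)


def cnv_score(matrix: pd.DataFrame | np.ndarray) -> pd.Series | float:
    """Mean of squared inferred-CNV values, per cell."""
    if isinstance(matrix, pd.DataFrame):
        return (matrix**2).mean(axis=1).rename("cnv_score")
    arr = np.asarray(matrix, dtype=float)
    if arr.size == 0:
        raise ValueError("empty CNV profile")
    return float(np.mean(arr**2, axis=-1)) if arr.ndim == 1 else np.mean(arr**2, axis=1)


def _reference_profile(matrix: pd.DataFrame, score: pd.Series, params: CnvParams) -> tuple[pd.Series, pd.Index]:
    n_top = max(1, int(np.ceil(params.top_score_fraction * len(score))))
    top_cells = score.sort_values(ascending=False, kind="stable").index[:n_top]
    return matrix.loc[top_cells].mean(axis=0), top_cells


def _correlate(matrix: pd.DataFrame, reference: pd.Series) -> pd.Series:
    ref = reference.to_numpy(float)
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    X = matrix.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * ref_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ ref_c) / denom
    return pd.Series(r, index=matrix.index, name="cnv_correlation")


def malignancy_call(
    matrix: pd.DataFrame,
    chromosomes: pd.Series,
    params: CnvParams | None = None,
) -> CnvResult:
    """Score, correlate against the top-score reference, and call cells.

    Calls follow the strict two-cutoff rule: tumor iff both score and
    correlation are strictly above their cutoffs, non-tumor iff both are
    strictly below; anything else -- including values exactly at a cutoff or
    an undefined correlation -- is undetermined.
    """
    params = params or CnvParams()
    score = cnv_score(matrix)
    reference, _ = _reference_profile(matrix, score, params)
    if float(reference.std(ddof=0)) == 0.0:
        logger.error("reference profile is constant; correlations undefined, all calls undetermined")
        correlation = pd.Series(np.nan, index=matrix.index, name="cnv_correlation")
    else:
        correlation = _correlate(matrix, reference)
    call = call_from_cutoffs(score, correlation, params)
    return CnvResult(
        matrix=matrix,
        chromosomes=chromosomes,
        score=score,
        correlation=correlation,
        call=call,
        reference_profile=reference,
        calibrated=False,
        params=params,
    )


def call_from_cutoffs(
    score: pd.Series, correlation: pd.Series, params: CnvParams | None = None
) -> pd.Series:
    """The two-cutoff decision rule on (score, correlation) pairs.

    Strict inequalities: a value exactly at its cutoff, or an undefined
    (NaN) correlation, can satisfy neither branch and yields undetermined.
    """
    params = params or CnvParams()
    call = pd.Series(UNDETERMINED, index=score.index, name="call")
    call[(score > params.score_cutoff) & (correlation > params.correlation_cutoff)] = TUMOR
    call[(score < params.score_cutoff) & (correlation < params.correlation_cutoff)] = NON_TUMOR
    return call


def recalibrate(result: CnvResult) -> CnvResult:
    """One recalibration pass using the called non-tumor cells as reference.

    Subtracts the per-gene mean of the non-tumor cells from every cell's
    inferred CNV, then recomputes scores, reference, correlations and calls
    once.  If no cell was called non-tumor the input is returned unchanged,
    flagged uncalibrated, with a warning.
    """
    non_tumor = result.call.index[result.call == NON_TUMOR]
    if len(non_tumor) == 0:
        warnings.warn("no non-tumor cells to recalibrate against; output left uncalibrated")
        return result
    baseline = result.matrix.loc[non_tumor].mean(axis=0)
    recal = malignancy_call(result.matrix - baseline, result.chromosomes, result.params)
    recal.calibrated = True
    return recal


class CnvMalignancyCaller(BaseEstimator):
    """Sklearn-style wrapper around the full CNV inference chain.

    Parameters mirror :class:`CnvParams`; ``positions`` is the gene-position
    table (index gene_id, columns chromosome/start) fixing the genomic order.

    After ``fit(X)`` (X = cells x genes log-normalized expression, AnnData or
    DataFrame) the fitted attributes hold the transductive result:
    ``cnv_matrix_``, ``score_``, ``correlation_``, ``labels_`` (calls),
    ``reference_profile_``, ``result_``.
    """

    def __init__(
        self,
        positions: pd.DataFrame | None = None,
        low_expression_mean_min: float = 0.2,
        clip_abs: float = 3.0,
        window_genes: int = 100,
        top_score_fraction: float = 0.05,
        score_cutoff: float = 0.02,
        correlation_cutoff: float = 0.2,
        recalibrate: bool = True,
        chromosome_order: list[str] | None = None,
    ):
        self.positions = positions
        self.low_expression_mean_min = low_expression_mean_min
        self.clip_abs = clip_abs
        self.window_genes = window_genes
        self.top_score_fraction = top_score_fraction
        self.score_cutoff = score_cutoff
        self.correlation_cutoff = correlation_cutoff
        self.recalibrate = recalibrate
        self.chromosome_order = chromosome_order

    def _params(self) -> CnvParams:
        return CnvParams(
            low_expression_mean_min=self.low_expression_mean_min,
            clip_abs=self.clip_abs,
            window_genes=self.window_genes,
            top_score_fraction=self.top_score_fraction,
            score_cutoff=self.score_cutoff,
            correlation_cutoff=self.correlation_cutoff,
            chromosome_order=self.chromosome_order,
        )

    def fit(self, X, y=None):
        if self.positions is None:
            raise ValueError("CnvMalignancyCaller requires a gene-position table")
        params = self._params()
        prepared, chrom = prepare_expression(X, self.positions, params)
        smoothed = moving_average(prepared, chrom, params)
        result = malignancy_call(smoothed, chrom, params)
        if self.recalibrate:
            result = recalibrate(result)
        self.result_ = result
        self.cnv_matrix_ = result.matrix
        self.score_ = result.score
        self.correlation_ = result.correlation
        self.labels_ = result.call
        self.reference_profile_ = result.reference_profile
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        """Fit and return the per-cell {tumor, non-tumor, undetermined} call."""
        return self.fit(X).labels_
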