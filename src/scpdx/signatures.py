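"""Gene-set scoring, cell-cycle classification, subtyping, composition tests.

The enrichment score is a per-cell rank statistic: genes are ranked by
expression within the cell (ties averaged) and the score is the difference
between the mean rank of in-set genes and the mean rank of out-of-set genes,
rescaled by its maximum attainable value so scores live in [-1, 1].  Positive
means the set is enriched among the cell's highly expressed genes.  Being
rank-based, the score is invariant to any strictly monotone per-cell
transform of expression, and only its sign feeds the cell-cycle rule, so any
monotone-equivalent scoring yields the same classification.

Cell-cycle states follow the two-score rule: cycling if both the G1/S and
G2/M scores are positive, non-cycling if both are negative, intermediate
otherwise (exact zeros are intermediate).

Molecular subtype of a bulk profile = the subtype centroid with the highest
significant (two-sided p < 0.05) Pearson correlation over that subtype's
signature genes; no significant centroid -> "unclassified".

Composition shifts between two groups of per-category cell counts are tested
with Pearson's chi-squared (no continuity correction), df = k - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import _dense

__all__ = [
    "GeneSetScorer",
    "enrichment_score",
    "CellCycleState",
    "classify_cycle",
    "score_cycle",
    "SubtypeClassifier",
    "assign_subtype",
    "composition_test",
]

CYCLING, NON_CYCLING, INTERMEDIATE = "cycling", "non-cycling", "intermediate"
UNCLASSIFIED = "unclassified"


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ad.AnnData):
        return pd.DataFrame(_dense(X.X), index=X.obs_names, columns=X.var_names)
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class GeneSetScorer(TransformerMixin, BaseEstimator):
    """Rank-difference enrichment scores for a collection of gene sets.

    ``transform(X)`` maps cells x genes expression to cells x sets scores in
    [-1, 1].  Set genes absent from the matrix are dropped with a warning; a
    set with no gene present, or covering every gene, is an error.
    """

    def __init__(self, gene_sets: dict[str, list[str]]):
        self.gene_sets = gene_sets

    def fit(self, X, y=None):
        frame = _as_frame(X)
        self.columns_ = frame.columns
        self.members_: dict[str, np.ndarray] = {}
        for name, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            mask = frame.columns.isin(genes)
            n_absent = len(set(genes)) - int(mask.sum())
            if n_absent:
                warnings.warn(f"gene set {name!r}: {n_absent} genes absent, dropped")
            if not mask.any():
                raise ValueError(f"gene set {name!r}: no member gene present in the matrix")
            if mask.all():
                raise ValueError(f"gene set {name!r} covers all genes; score undefined")
            self.members_[name] = mask
        return self

    def transform(self, X) -> pd.DataFrame:
        frame = _as_frame(X)
        if not frame.columns.equals(self.columns_):
            raise ValueError("transform matrix genes differ from fit matrix genes")
        values = frame.to_numpy(float)
        ranks = stats.rankdata(values, axis=1)  # average ranks 1..G
        G = values.shape[1]
        out = {}
        for name, mask in self.members_.items():
            k = int(mask.sum())
            mean_in = ranks[:, mask].mean(axis=1)
            mean_out = ranks[:, ~mask].mean(axis=1)
            # max |mean_in - mean_out| = G/2, attained when the set occupies
            # the extreme ranks, for any set size
            out[name] = (mean_in - mean_out) / (G / 2.0)
        return pd.DataFrame(out, index=frame.index)

    def fit_transform(self, X, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)


def enrichment_score(X, gene_set: list[str]) -> pd.Series:
    """Per-cell rank-difference enrichment score for one gene set."""
    return GeneSetScorer({"set": list(gene_set)}).fit_transform(X)["set"].rename("score")


@dataclass
class CellCycleState:
    g1s_score: float
    g2m_score: float
    state: str


def classify_cycle(g1s_score, g2m_score):
    """Two-score cell-cycle rule (strict inequalities; zeros -> intermediate)."""
    g1s = np.asarray(g1s_score, dtype=float)
    g2m = np.asarray(g2m_score, dtype=float)
    if not (np.all(np.isfinite(g1s)) and np.all(np.isfinite(g2m))):
        raise ValueError("cycle scores must be finite")
    state = np.where(
        (g1s > 0) & (g2m > 0),
        CYCLING,
        np.where((g1s < 0) & (g2m < 0), NON_CYCLING, INTERMEDIATE),
    )
    if np.ndim(g1s_score) == 0:
        return CellCycleState(float(g1s), float(g2m), str(state))
    return pd.Series(state, name="cycle_state")


def score_cycle(X, g1s_genes: list[str], g2m_genes: list[str]) -> pd.DataFrame:
    """Score the G1/S and G2/M programs and classify each cell."""
    scores = GeneSetScorer({"G1S": list(g1s_genes), "G2M": list(g2m_genes)}).fit_transform(X)
    states = classify_cycle(scores["G1S"].to_numpy(), scores["G2M"].to_numpy())
    return pd.DataFrame(
        {"g1s_score": scores["G1S"], "g2m_score": scores["G2M"], "state": states.to_numpy()},
        index=scores.index,
    )


class SubtypeClassifier(BaseEstimator):
    """Molecular subtyping of bulk profiles by signature correlation.

    ``centroids`` is genes x subtypes; each column holds the subtype's
    average signature-gene expression, NaN on genes outside that subtype's
    signature.  ``predict(X)`` (samples x genes) assigns each sample the
    subtype with the highest Pearson r among those with two-sided p <
    ``alpha``; ties break by column order with a warning; no significant
    subtype -> "unclassified".

    Fitted attributes after predict: ``correlations_`` and ``pvalues_``
    (samples x subtypes).
    """

    def __init__(self, centroids: pd.DataFrame | None = None, alpha: float = 0.05, min_shared_genes: int = 3):
        self.centroids = centroids
        self.alpha = alpha
        self.min_shared_genes = min_shared_genes

    def fit(self, X=None, y=None):
        """X, y optional: reference profiles (samples x genes) and their
        subtype labels, averaged into centroids when no centroid table was
        given."""
        if self.centroids is not None:
            self.centroids_ = self.centroids
        else:
            if X is None or y is None:
                raise ValueError("either centroids or labelled reference profiles are required")
            frame = _as_frame(X)
            self.centroids_ = frame.groupby(pd.Series(y, index=frame.index)).mean().T
        return self

    def predict(self, X) -> pd.Series:
        if not hasattr(self, "centroids_"):
            self.fit()
        samples = _as_frame(X)
        subtypes = list(self.centroids_.columns)
        r = pd.DataFrame(np.nan, index=samples.index, columns=subtypes)
        p = pd.DataFrame(np.nan, index=samples.index, columns=subtypes)
        for subtype in subtypes:
            centroid = self.centroids_[subtype].dropna()
            shared = samples.columns.intersection(centroid.index)
            if len(shared) < self.min_shared_genes:
                warnings.warn(
                    f"subtype {subtype!r}: only {len(shared)} shared signature genes, skipped"
                )
                continue
            c = centroid[shared].to_numpy(float)
            for sample in samples.index:
                v = samples.loc[sample, shared].to_numpy(float)
                if np.std(v) == 0 or np.std(c) == 0:
                    continue
                res = stats.pearsonr(v, c)
                r.loc[sample, subtype] = res.statistic
                p.loc[sample, subtype] = res.pvalue
        self.correlations_ = r
        self.pvalues_ = p
        calls = []
        for sample in samples.index:
            significant = r.columns[(p.loc[sample] < self.alpha).fillna(False)]
            if len(significant) == 0:
                calls.append(UNCLASSIFIED)
                continue
            best = r.loc[sample, significant].max()
            winners = [s for s in significant if r.loc[sample, s] == best]
            if len(winners) > 1:
                warnings.warn(f"sample {sample}: subtype tie {winners}, assigning {winners[0]}")
            calls.append(winners[0])
        return pd.Series(calls, index=samples.index, name="subtype")


def assign_subtype(bulk_profile: pd.Series, centroids: pd.DataFrame, alpha: float = 0.05):
    """Subtype one bulk profile; returns (call, correlations, pvalues)."""
    clf = SubtypeClassifier(centroids=centroids, alpha=alpha).fit()
    frame = bulk_profile.to_frame().T
    call = clf.predict(frame)
    return call.iloc[0], clf.correlations_.iloc[0], clf.pvalues_.iloc[0]


def composition_test(counts_a: pd.Series, counts_b: pd.Series) -> tuple[float, int, float]:
    """Pearson chi-squared test on the 2 x k table of per-category cell counts."""
    counts_a = pd.Series(counts_a)
    counts_b = pd.Series(counts_b)
    categories = counts_a.index.union(counts_b.index)
    if len(categories) < 2:
        raise ValueError("composition test needs at least 2 categories")
    table = np.vstack(
        [
            counts_a.reindex(categories, fill_value=0).to_numpy(float),
            counts_b.reindex(categories, fill_value=0).to_numpy(float),
        ]
    )
    if table.sum(axis=1).min() <= 0:
        raise ValueError("both groups need a positive total count")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        empty = [str(categories[i]) for i in np.flatnonzero(expected.min(axis=0) == 0)]
        raise ValueError(f"expected count of zero for categories {empty}; merge categories")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
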