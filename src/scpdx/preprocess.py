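"""Normalization, variable genes, graph clustering, annotation and DE.

The processing chain is the standard droplet workflow: a gene-prevalence
filter (genes expressed in >=1% of cells), depth normalization to TPM-like
values (per-cell scaling to 1e6 total, no gene-length correction) followed by
log2(x+1), binned mean/dispersion variable-gene selection, PCA on scaled
variable genes, kNN-graph Leiden clustering, marker-based cluster annotation,
and per-gene Welch t-test differential expression with Bonferroni control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "gene_prevalence_filter",
    "tpm_like",
    "select_variable_genes",
    "GraphClusterer",
    "reduce_and_cluster",
    "annotate_clusters",
    "differential_expression",
    "ClusterResult",
]

SCALE_FACTOR = 1e6


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def gene_prevalence_filter(adata: ad.AnnData, min_fraction: float = 0.01) -> ad.AnnData:
    """Keep genes with a nonzero count in at least ``min_fraction`` of cells
    (inclusive boundary: 2 of 200 cells passes at 1%)."""
    if adata.n_obs < 100:
        warnings.warn(
            f"prevalence filter on only {adata.n_obs} cells; the "
            f"{min_fraction:.0%} threshold is degenerate below 100 cells"
        )
    expressed = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    keep = expressed >= min_fraction * adata.n_obs
    return adata[:, keep].copy()


def tpm_like(adata: ad.AnnData) -> ad.AnnData:
    """Transform counts to log2(1 + 1e6 * count / cell_total).

    Depth-invariant per cell: doubling all counts of a cell leaves its
    normalized vector unchanged.  Raises on zero-depth cells, which QC
    should already have removed.
    """
    counts = _dense(adata.X).astype(float)
    depth = counts.sum(axis=1)
    if np.any(depth <= 0):
        bad = adata.obs_names[depth <= 0][:5].tolist()
        raise ValueError(f"zero-depth cells cannot be normalized, e.g. {bad}")
    norm = ad.AnnData(
        X=np.log2(1.0 + SCALE_FACTOR * counts / depth[:, None]),
        obs=adata.obs.copy(),
        var=adata.var.copy(),
    )
    norm.uns.update(adata.uns)
    norm.uns["normalized"] = True
    norm.uns["scale_factor"] = SCALE_FACTOR
    return norm


def select_variable_genes(
    norm: ad.AnnData,
    n_bins: int = 20,
    dispersion_z_cutoff: float = 1.0,
    n_top: int | None = None,
) -> list[str]:
    """Variable genes by binned mean/dispersion, Seurat-style.

    Genes are binned by mean expression into ``n_bins`` equal-count bins;
    the dispersion (variance/mean) is z-scored within each bin and genes
    above ``dispersion_z_cutoff`` are selected (or the ``n_top`` highest-z
    genes if given).  Constant genes are never selected.  Deterministic and
    invariant to cell order.
    """
    if norm.n_obs < 2:
        raise ValueError("need at least two cells to estimate dispersion")
    X = _dense(norm.X)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    usable = (var > 0) & (mean > 0)
    # equal-count bins on mean expression of usable genes
    order = pd.Series(mean, index=norm.var_names)
    bins = pd.qcut(order[usable], q=min(n_bins, usable.sum()), duplicates="drop")
    disp = pd.Series(dispersion, index=norm.var_names)[usable]
    grouped = disp.groupby(bins, observed=True)
    z = (disp - grouped.transform("mean")) / grouped.transform("std").replace(0.0, np.nan)
    z = z.dropna()
    if n_top is not None:
        return z.sort_values(ascending=False).index[:n_top].tolist()
    selected = z[z > dispersion_z_cutoff].sort_values(ascending=False)
    return selected.index.tolist()


@dataclass
class ClusterResult:
    labels: pd.Series  # per-cell cluster id
    cluster_types: pd.Series | None  # per-cluster cell-type label (after annotation)
    pc_loadings: np.ndarray  # genes x n_pcs
    embedding: np.ndarray  # cells x n_pcs
    variable_genes: list[str]


class GraphClusterer(ClusterMixin, BaseEstimator):
    """PCA + kNN-graph Leiden community detection, sklearn-style.

    Parameters
    ----------
    n_pcs : number of principal components of the scaled variable-gene
        matrix used for the neighbor graph (20 by default, the depth at
        which droplet data's informative variance typically saturates).
    resolution : Leiden modularity resolution.
    n_neighbors : size of the kNN neighborhood.
    random_state : seed for PCA solver and Leiden refinement.

    Fitted attributes: ``labels_`` (cluster id per cell), ``embedding_``
    (cells x n_pcs), ``components_`` (n_pcs x genes loadings).
    """

    def __init__(self, n_pcs: int = 20, resolution: float = 0.5, n_neighbors: int = 15, random_state: int = 0):
        self.n_pcs = n_pcs
        self.resolution = resolution
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit(self, X, y=None):
        """X: cells x genes array/DataFrame of normalized expression
        (already restricted to variable genes)."""
        if isinstance(X, ad.AnnData):
            values, index = _dense(X.X), X.obs_names
        elif isinstance(X, pd.DataFrame):
            values, index = X.to_numpy(float), X.index
        else:
            values = np.asarray(X, dtype=float)
            index = pd.RangeIndex(values.shape[0])
        if values.shape[0] < self.n_pcs:
            raise ValueError(
                f"{values.shape[0]} cells < n_pcs={self.n_pcs}; reduce n_pcs"
            )
        if values.shape[1] < self.n_pcs:
            raise ValueError(
                f"{values.shape[1]} genes < n_pcs={self.n_pcs}; provide more variable genes"
            )
        work = ad.AnnData(X=values.copy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sc.pp.scale(work, max_value=10)
        work.X = np.nan_to_num(work.X)  # zero-variance genes scale to 0
        sc.tl.pca(work, n_comps=self.n_pcs, svd_solver="arpack", random_state=self.random_state)
        sc.pp.neighbors(work, n_neighbors=self.n_neighbors, n_pcs=self.n_pcs, random_state=self.random_state)
        sc.tl.leiden(
            work,
            resolution=self.resolution,
            random_state=self.random_state,
            flavor="leidenalg",
            n_iterations=-1,
        )
        self.labels_ = pd.Series(work.obs["leiden"].astype(str).to_numpy(), index=index, name="cluster")
        self.embedding_ = work.obsm["X_pca"].copy()
        self.components_ = work.varm["PCs"].T.copy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()


def reduce_and_cluster(
    norm: ad.AnnData,
    variable_genes: list[str],
    n_pcs: int = 20,
    resolution: float = 0.5,
    n_neighbors: int = 15,
    seed: int = 0,
) -> ClusterResult:
    """Cluster cells on the PCA embedding of scaled variable genes."""
    if len(variable_genes) < n_pcs:
        raise ValueError(f"{len(variable_genes)} variable genes < n_pcs={n_pcs}")
    sub = norm[:, variable_genes]
    clusterer = GraphClusterer(
        n_pcs=n_pcs, resolution=resolution, n_neighbors=n_neighbors, random_state=seed
    ).fit(sub)
    return ClusterResult(
        labels=clusterer.labels_,
        cluster_types=None,
        pc_loadings=clusterer.components_.T,
        embedding=clusterer.embedding_,
        variable_genes=list(variable_genes),
    )


def annotate_clusters(
    norm: ad.AnnData,
    labels: pd.Series,
    marker_map: dict[str, list[str]],
) -> pd.Series:
    """Label each cluster with the cell type whose marker-set mean expression
    (averaged over the cluster's cells) is highest; ties break alphabetically
    with a warning."""
    X = pd.DataFrame(_dense(norm.X), index=norm.obs_names, columns=norm.var_names)
    scores = {}
    any_present = False
    for ctype, markers in sorted(marker_map.items()):
        present = [g for g in markers if g in X.columns]
        missing = set(markers) - set(present)
        if missing:
            warnings.warn(f"{ctype}: {len(missing)} marker genes absent, dropped")
        if not present:
            continue
        any_present = True
        scores[ctype] = X[present].mean(axis=1)
    if not any_present:
        raise ValueError("no marker gene of any cell type is present in the matrix")
    score_df = pd.DataFrame(scores)
    out = {}
    for cluster in sorted(labels.unique()):
        cluster_scores = score_df.loc[labels[labels == cluster].index].mean(axis=0)
        best = cluster_scores.max()
        winners = sorted(cluster_scores.index[cluster_scores == best])
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cluster}: tie between {winners}, assigning {winners[0]}"
            )
        out[cluster] = winners[0]
    return pd.Series(out, name="cell_type")


def differential_expression(
    norm: ad.AnnData,
    group_a,
    group_b,
    min_fraction: float = 0.1,
    min_logfc: float = 0.25,
    highlight_logfc: float = 0.8,
    highlight_p: float = 1e-3,
) -> pd.DataFrame:
    """Per-gene Welch two-sample t test on log-normalized expression.

    Genes are pre-filtered to those expressed (value > 0) in at least
    ``min_fraction`` of either group and with |log2 fold change| >=
    ``min_logfc`` (set both to 0 to test every gene).  P values are
    Bonferroni-adjusted over the tested genes.  The ``highlight`` flag marks
    genes with |logFC| > 0.8 and p < 0.001, the convention used for volcano
    reporting.
    """
    group_a = pd.Index(group_a)
    group_b = pd.Index(group_b)
    if set(group_a) == set(group_b):
        raise ValueError("group_a and group_b are identical")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    X = pd.DataFrame(_dense(norm.X), index=norm.obs_names, columns=norm.var_names)
    A = X.loc[group_a].to_numpy()
    B = X.loc[group_b].to_numpy()
    logfc = A.mean(axis=0) - B.mean(axis=0)
    frac_a = (A > 0).mean(axis=0)
    frac_b = (B > 0).mean(axis=0)
    tested = (np.maximum(frac_a, frac_b) >= min_fraction) & (np.abs(logfc) >= min_logfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A[:, tested], B[:, tested], equal_var=False, axis=0)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    result = pd.DataFrame(
        {
            "gene": np.asarray(norm.var_names)[tested],
            "logfc": logfc[tested],
            "t": t,
            "p": p,
            "p_adj": np.minimum(1.0, p * tested.sum()),
        }
    ).set_index("gene")
    result["highlight"] = (np.abs(result["logfc"]) > highlight_logfc) & (
        result["p"] < highlight_p
    )
    return result.sort_values("p")
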