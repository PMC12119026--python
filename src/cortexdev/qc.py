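"""Multi-round quality control and cluster purification.

The pipeline retains cells by strict library-size/complexity bounds, drops
rarely detected genes, normalizes each cell to a fixed total followed by
log1p, clusters (HVG -> z-score -> PCA -> kNN graph -> Leiden), removes
whole clusters dominated by mitochondrial transcripts, and finally purifies
clusters using a reference mapping: diffusely mapping clusters are removed
whole, and within retained clusters the cells of any mapped label making up
less than a minimum share of the cluster are removed.

All filters preserve input order and are idempotent; every threshold and
removal count is returned for the run manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

__all__ = [
    "compute_qc_metrics",
    "filter_cells",
    "filter_genes",
    "normalize_log",
    "cluster_pipeline",
    "remove_mito_clusters",
    "purify_by_mapping",
    "naive_doublet_score",
    "ClusterAssignment",
]


def compute_qc_metrics(adata: ad.AnnData) -> ad.AnnData:
    """Add n_counts, n_genes and percent_mito to ``.obs`` (from raw counts)."""
    X = sp.csr_matrix(adata.X)
    X.eliminate_zeros()
    adata.obs["n_counts"] = np.asarray(X.sum(axis=1)).ravel().astype(int)
    adata.obs["n_genes"] = np.diff(X.indptr)
    if "is_mito" in adata.var:
        mito = X[:, adata.var["is_mito"].to_numpy().astype(bool)]
        mito_counts = np.asarray(mito.sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        adata.obs["percent_mito"] = np.where(
            adata.obs["n_counts"] > 0, mito_counts / adata.obs["n_counts"], 0.0)
    return adata


def filter_cells(adata: ad.AnnData, max_genes: int = 7000, max_counts: int = 40000,
                 min_counts: int = 500) -> ad.AnnData:
    """Retain cells with n_genes < max_genes, min_counts < n_counts < max_counts.

    All inequalities are strict. Order is preserved.
    """
    if min(max_genes, max_counts, min_counts) <= 0 or min_counts >= max_counts:
        raise ValueError("thresholds must be positive with min_counts < max_counts")
    if "n_counts" not in adata.obs:
        compute_qc_metrics(adata)
    keep = ((adata.obs["n_genes"] < max_genes)
            & (adata.obs["n_counts"] < max_counts)
            & (adata.obs["n_counts"] > min_counts)).to_numpy()
    if not keep.any():
        warnings.warn("all cells removed by filter_cells")
    return adata[keep].copy()


def filter_genes(adata: ad.AnnData, min_cells: int = 100) -> ad.AnnData:
    """Remove genes detected (nonzero) in fewer than ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    X = sp.csc_matrix(adata.X)
    n_cells = np.diff(X.indptr)
    return adata[:, n_cells >= min_cells].copy()


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Rescale each cell to ``target_sum`` total counts, then log1p.

    Raw counts are kept in ``.layers['counts']``. Cells with zero counts
    must be filtered first.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("zero-count cell encountered; run filter_cells first")
    out = adata.copy()
    out.layers["counts"] = sp.csr_matrix(adata.X)
    scale = target_sum / totals
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    out.X = X.tocsr()
    out.uns["normalization"] = {"target_sum": target_sum, "log_base": "e", "transform": "log1p"}
    return out


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # per-cell integer cluster ids, contiguous from 0
    resolution: float
    summaries: pd.DataFrame       # per-cluster size, mean percent_mito, mean doublet_score
    params: dict = field(default_factory=dict)


def cluster_pipeline(adata: ad.AnnData, n_hvg: int = 2000, n_pcs: int = 40,
                     k_neighbors: int = 15, resolution: float = 1.0,
                     seed: int = 0) -> ClusterAssignment:
    """HVG selection, z-scoring, PCA, kNN graph and Leiden clustering.

    Expects log1p-normalized expression in ``.X``. Deterministic given the
    seed. HVGs are selected by mean-dispersion binning.
    """
    if adata.n_obs < k_neighbors:
        raise ValueError("fewer cells than k_neighbors")
    n_pcs = min(n_pcs, adata.n_obs - 1, adata.n_vars - 1)
    tmp = adata.copy()
    sc.pp.highly_variable_genes(tmp, n_top_genes=min(n_hvg, tmp.n_vars), flavor="seurat")
    tmp = tmp[:, tmp.var["highly_variable"]].copy()
    sc.pp.scale(tmp, max_value=10)
    sc.tl.pca(tmp, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(tmp, n_neighbors=k_neighbors, random_state=seed)
    sc.tl.leiden(tmp, resolution=resolution, random_state=seed,
                 flavor="igraph", n_iterations=2, directed=False)
    labels = tmp.obs["leiden"].astype(int).to_numpy()
    # relabel contiguous from 0 in order of first appearance stability
    uniq = np.unique(labels)
    remap = {old: new for new, old in enumerate(uniq)}
    labels = np.array([remap[v] for v in labels])
    summaries = _cluster_summaries(adata, labels)
    params = {"n_hvg": n_hvg, "n_pcs": n_pcs, "k_neighbors": k_neighbors,
              "resolution": resolution, "seed": seed}
    return ClusterAssignment(labels=labels, resolution=resolution,
                             summaries=summaries, params=params)


def _cluster_summaries(adata: ad.AnnData, labels: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"cluster": labels})
    if "percent_mito" in adata.obs:
        df["percent_mito"] = adata.obs["percent_mito"].to_numpy()
    if "doublet_score" in adata.obs:
        df["doublet_score"] = adata.obs["doublet_score"].to_numpy()
    g = df.groupby("cluster")
    out = g.size().to_frame("size")
    for col in ("percent_mito", "doublet_score"):
        if col in df:
            out[f"mean_{col}"] = g[col].mean()
    return out


def remove_mito_clusters(adata: ad.AnnData, clusters: ClusterAssignment,
                         mito_threshold: float = 0.2) -> tuple[ad.AnnData, np.ndarray]:
    """Remove whole clusters whose mean mitochondrial fraction >= threshold."""
    if len(clusters.labels) != adata.n_obs:
        raise ValueError("clusters were not computed on the current cells")
    means = clusters.summaries["mean_percent_mito"]
    bad = set(means.index[means >= mito_threshold])
    keep = ~np.isin(clusters.labels, list(bad))
    return adata[keep].copy(), clusters.labels[keep]


def purify_by_mapping(
    adata: ad.AnnData,
    clusters: np.ndarray,
    mapping: pd.DataFrame,
    min_component: float = 0.02,
    diffuse_max_share: float = 0.5,
    diffuse_mean_prob: float = 0.5,
) -> tuple[ad.AnnData, dict]:
    """Purify clusters using a reference label transfer.

    ``mapping`` must cover all cells (index aligned to ``adata.obs_names``)
    with columns ``assigned`` and ``max_prob``. A cluster is diffuse — and
    removed whole — when its most common mapped label accounts for less
    than ``diffuse_max_share`` of cells AND its mean top assignment
    probability is below ``diffuse_mean_prob``. In retained clusters, cells
    whose mapped label accounts for less than ``min_component`` of the
    cluster are removed.
    """
    if not set(adata.obs_names) <= set(mapping.index):
        raise ValueError("mapping does not cover all cells")
    mapping = mapping.loc[adata.obs_names]
    clusters = np.asarray(clusters)
    keep = np.ones(adata.n_obs, dtype=bool)
    removed = {"diffuse_clusters": [], "minor_component_cells": 0}
    for c in np.unique(clusters):
        in_c = clusters == c
        labs = mapping.loc[in_c, "assigned"]
        shares = labs.value_counts(normalize=True)
        if shares.iloc[0] < diffuse_max_share and \
                mapping.loc[in_c, "max_prob"].mean() < diffuse_mean_prob:
            keep[in_c] = False
            removed["diffuse_clusters"].append(int(c))
            continue
        minor = shares.index[shares < min_component]
        drop = in_c & labs.reindex(mapping.index[in_c]).isin(minor).reindex(
            adata.obs_names, fill_value=False).to_numpy()
        removed["minor_component_cells"] += int(drop.sum())
        keep &= ~drop
    return adata[keep].copy(), removed


def naive_doublet_score(adata: ad.AnnData, n_sim: int = 200, seed: int = 0) -> np.ndarray:
    """Plumbing stand-in for an external doublet caller.

    Scores each cell by its Pearson correlation to the nearest of ``n_sim``
    synthetic doublet profiles (normalized sums of random cell pairs). Not
    a re-implementation of any published doublet algorithm; use a real
    doublet score column when one is available.
    """
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1
    Xn = sp.diags(1.0 / totals) @ X
    i1 = rng.integers(0, adata.n_obs, n_sim)
    i2 = rng.integers(0, adata.n_obs, n_sim)
    D = np.asarray((Xn[i1] + Xn[i2]).todense()) / 2.0
    Xd = np.asarray(Xn.todense())
    Xd = (Xd - Xd.mean(axis=1, keepdims=True))
    D = (D - D.mean(axis=1, keepdims=True))
    Xd /= np.linalg.norm(Xd, axis=1, keepdims=True) + 1e-12
    D /= np.linalg.norm(D, axis=1, keepdims=True) + 1e-12
    return (Xd @ D.T).max(axis=1)
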