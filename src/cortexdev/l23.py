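"""Continuum analysis of a subclass with graded type identity (L2/3-style).

Per-type markers (one-vs-rest rank-sum, FC > 1.5, FDR < 0.05, expressed in
>20% of the type's cells) define a fixed feature set; PCA is run
independently per condition on centered marker expression; eigenvector
correspondence across conditions is the |dot product| of loadings (equal to
the loading correlation for orthonormal eigenvectors); per-cell type scores
are mean marker expression; distribution shifts along the continuum are
tested with two-sample Kolmogorov-Smirnov statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .de import one_vs_rest

__all__ = [
    "select_type_markers",
    "pca_condition",
    "eigenvector_correspondence",
    "marker_score",
    "ks_compare",
    "pc1_profile",
    "Embedding",
]


def select_type_markers(x, type_labels, gene_names, min_fc: float = 1.5,
                        min_frac: float = 0.2, alpha: float = 0.05) -> dict:
    """Up-regulated one-vs-rest markers per type, plus their union.

    A marker must pass FC > min_fc (up in the type), FDR < alpha, and be
    expressed in more than ``min_frac`` of the type's cells. The union is
    the PCA feature set, held fixed across all conditions compared.
    """
    type_labels = np.asarray(type_labels)
    if len(pd.unique(type_labels)) < 2:
        raise ValueError("need at least two types")
    tab = one_vs_rest(x, type_labels, gene_names=gene_names,
                      min_frac=min_frac, min_fc=min_fc, alpha=alpha)
    t = np.log2(min_fc)
    sel = tab[(tab["log2fc"] > t) & (tab["fdr"] < alpha)
              & (tab["frac_expr_a"] > min_frac)]
    markers = {g: list(sub["gene"]) for g, sub in sel.groupby("group")}
    for ty in pd.unique(type_labels):
        markers.setdefault(str(ty), [])
    union: list = []
    for g in sorted(markers):
        union.extend(m for m in markers[g] if m not in union)
    if not union:
        raise ValueError("no markers found for any type")
    markers["union"] = union
    return markers


@dataclass
class Embedding:
    feature_genes: list
    loadings: np.ndarray          # (n_components, n_features), orthonormal rows
    scores: np.ndarray            # (n_cells, n_components)
    variance_fraction: np.ndarray


def _feature_matrix(x, gene_names, feature_genes) -> np.ndarray:
    col = {g: i for i, g in enumerate(gene_names)}
    n = x.shape[0]
    out = np.zeros((n, len(feature_genes)))
    xc = x.tocsc() if sp.issparse(x) else np.asarray(x, dtype=float)
    missing = 0
    for j, g in enumerate(feature_genes):
        if g in col:
            cj = xc[:, col[g]]
            out[:, j] = np.asarray(cj.todense()).ravel() if sp.issparse(cj) else cj
        else:
            missing += 1
    if missing:
        import warnings
        warnings.warn(f"{missing} feature gene(s) missing; zero-filled")
    return out


def pca_condition(x, gene_names, feature_genes, n_components: int = 4,
                  scale: bool = False) -> Embedding:
    """Centered PCA on the marker submatrix of one condition.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are deterministic.
    """
    F = _feature_matrix(x, gene_names, feature_genes)
    if F.shape[0] < n_components:
        raise ValueError("fewer cells than components")
    if scale:
        sd = F.std(axis=0)
        sd[sd == 0] = 1.0
        F = F / sd
    pca = PCA(n_components=min(n_components, *F.shape), svd_solver="full")
    scores = pca.fit_transform(F)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(loadings.shape[0]),
                            np.abs(loadings).argmax(axis=1)])
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    return Embedding(feature_genes=list(feature_genes), loadings=loadings,
                     scores=scores,
                     variance_fraction=pca.explained_variance_ratio_)


def eigenvector_correspondence(e1: Embedding, e2: Embedding, n: int = 2):
    """n x n matrix of |dot products| between the two embeddings' loadings.

    Since loadings are orthonormal this equals the magnitude of the loading
    correlation (up to centering). Returns (matrix, one_to_one flag); the
    flag is True when the optimal assignment lies on the diagonal and each
    row/column max is diagonal.
    """
    if list(e1.feature_genes) != list(e2.feature_genes):
        raise ValueError("embeddings use different feature sets")
    M = np.abs(e1.loadings[:n] @ e2.loadings[:n].T)
    rows, cols = linear_sum_assignment(-M)
    one_to_one = bool(np.all(cols == rows)
                      and np.all(M.argmax(axis=1) == np.arange(M.shape[0]))
                      and np.all(M.argmax(axis=0) == np.arange(M.shape[1])))
    return M, one_to_one


def marker_score(x, gene_names, gene_set) -> np.ndarray:
    """Per-cell mean expression over a marker set."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    return _feature_matrix(x, gene_names, gene_set).mean(axis=1)


def ks_compare(scores_a, scores_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def pc1_profile(type_scores: dict, pc1: np.ndarray, condition_labels,
                window_frac: float = 0.10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-score profiles along PC1 plus cross-condition KS tests.

    ``type_scores`` maps type name -> per-cell score; ``pc1`` is each
    cell's continuum coordinate; curves are sliding-window means of each
    score over cells ordered by PC1, per condition. KS tests compare each
    type's score distribution between every pair of conditions; ``p_adj``
    is Bonferroni over all type x condition-pair tests in the call.
    """
    condition_labels = np.asarray(condition_labels)
    pc1 = np.asarray(pc1, dtype=float)
    conds = list(pd.unique(condition_labels))
    curves = []
    for cond in conds:
        sel = np.flatnonzero(condition_labels == cond)
        order = sel[np.argsort(pc1[sel], kind="stable")]
        w = max(1, int(round(window_frac * len(order))))
        kernel = np.ones(w) / w
        for ty, sc_vals in type_scores.items():
            v = np.asarray(sc_vals, dtype=float)[order]
            smooth = np.convolve(v, kernel, mode="valid") if len(v) >= w else v
            pos = np.sort(pc1[sel], kind="stable")
            pos = pos[(w - 1) // 2: (w - 1) // 2 + len(smooth)]
            curves.append(pd.DataFrame({"condition": cond, "type": ty,
                                        "pc1": pos, "score": smooth}))
    curves = pd.concat(curves, ignore_index=True)

    rows = []
    pairs = list(combinations(conds, 2))
    n_tests = max(1, len(pairs) * len(type_scores))
    for ca, cb in pairs:
        ia = condition_labels == ca
        ib = condition_labels == cb
        for ty, sc_vals in type_scores.items():
            v = np.asarray(sc_vals, dtype=float)
            D, p = ks_compare(v[ia], v[ib])
            rows.append({"condition_a": ca, "condition_b": cb, "type": ty,
                         "D": D, "p": p, "p_adj": min(1.0, p * n_tests)})
    return curves, pd.DataFrame(rows)
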