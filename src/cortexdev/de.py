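"""Wilcoxon rank-sum differential expression on normalized expression.

Conventions used throughout the package:

* ``x`` is a cells x genes matrix of log1p-normalized expression (sparse or
  dense); "expressed" means a nonzero entry.
* Fold changes are ratios of group means of de-logged normalized expression
  (``expm1`` of the log1p values) with a small pseudocount, reported as
  log2.
* p-values come from the two-sided rank-sum test: an exact rank-split
  enumeration when both groups have <= `exact_max_n` cells, otherwise the
  tie-corrected normal approximation with continuity correction.
* FDR is Benjamini-Hochberg within the candidate genes of one contrast
  (one call = one test family).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["fold_change", "de_test", "one_vs_rest", "exact_ranksum_p"]


def _to_dense(x, rows=None, cols=None) -> np.ndarray:
    if rows is not None:
        x = x[rows]
    if cols is not None:
        x = x[:, cols]
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


def _group_stats(x, idx, delog=True):
    """(mean of de-logged expression, fraction nonzero) per gene for a row subset."""
    xs = x[idx] if not isinstance(idx, slice) else x
    n = xs.shape[0]
    if sp.issparse(xs):
        xs = xs.tocsc()
        frac = np.diff(xs.indptr) / max(n, 1)
        if delog:
            data = np.expm1(xs.data)
            xs = sp.csc_matrix((data, xs.indices, xs.indptr), shape=xs.shape)
        mean = np.asarray(xs.sum(axis=0)).ravel() / max(n, 1)
    else:
        xs = np.asarray(xs, dtype=float)
        frac = (xs != 0).mean(axis=0) if n else np.zeros(xs.shape[1])
        mean = (np.expm1(xs) if delog else xs).mean(axis=0) if n else np.zeros(xs.shape[1])
    return mean, frac


def fold_change(x, cells_a, cells_b, pseudo: float = 1e-9, delog: bool = True) -> np.ndarray:
    """Per-gene log2 fold change of group a over group b.

    Means are taken over de-logged normalized expression; ``pseudo`` guards
    the all-zero case (both groups zero => log2fc = 0).
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("empty group")
    if np.intersect1d(cells_a, cells_b).size:
        raise ValueError("groups must be disjoint")
    ma, _ = _group_stats(x, cells_a, delog=delog)
    mb, _ = _group_stats(x, cells_b, delog=delog)
    return np.log2(ma + pseudo) - np.log2(mb + pseudo)


def exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all rank splits.

    Uses mid-ranks, so ties are handled; p is the fraction of the
    C(n_a+n_b, n_a) equally likely splits whose rank sum deviates from its
    null mean at least as much as the observed one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, ntot = len(a), len(pooled)
    obs = ranks[:na].sum()
    mu = na * (ntot + 1) / 2.0
    dev = abs(obs - mu) - 1e-12
    hits = total = 0
    for idx in combinations(range(ntot), na):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            hits += 1
    return hits / total


def de_test(
    x,
    cells_a,
    cells_b,
    min_frac: float = 0.4,
    min_fc: float = 2.0,
    alpha: float = 0.05,
    pseudo: float = 1e-9,
    exact_max_n: int = 8,
    gene_names=None,
    group: str = "",
    contrast: str = "",
    chunk: int = 512,
) -> pd.DataFrame:
    """Two-group differential expression table for one contrast.

    Candidate genes are those expressed (nonzero) in more than ``min_frac``
    of cells in at least one group. Significance requires fold change above
    ``min_fc`` (as a ratio, either direction) and BH FDR below ``alpha``.
    """
    if not (0 < min_frac < 1):
        raise ValueError("min_frac must be in (0,1)")
    if min_fc <= 1:
        raise ValueError("min_fc is a ratio and must exceed 1")
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("empty group")

    ma, fa = _group_stats(x, cells_a)
    mb, fb = _group_stats(x, cells_b)
    log2fc = np.log2(ma + pseudo) - np.log2(mb + pseudo)
    cand = np.flatnonzero((fa > min_frac) | (fb > min_frac))

    p = np.ones(len(cand))
    if len(cand):
        if len(cells_a) <= exact_max_n and len(cells_b) <= exact_max_n:
            A = _to_dense(x, cells_a, cand)
            B = _to_dense(x, cells_b, cand)
            p = np.array([exact_ranksum_p(A[:, j], B[:, j]) for j in range(len(cand))])
        else:
            ps = []
            for start in range(0, len(cand), chunk):
                cols = cand[start:start + chunk]
                A = _to_dense(x, cells_a, cols)
                B = _to_dense(x, cells_b, cols)
                res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided",
                                         method="asymptotic")
                ps.append(np.atleast_1d(res.pvalue))
            p = np.concatenate(ps)
    fdr = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    if gene_names is None:
        gene_names = np.arange(x.shape[1])
    gene_names = np.asarray(gene_names)
    lfc = log2fc[cand]
    t = np.log2(min_fc)
    out = pd.DataFrame({
        "gene": gene_names[cand],
        "group": group,
        "contrast": contrast,
        "log2fc": lfc,
        "frac_expr_a": fa[cand],
        "frac_expr_b": fb[cand],
        "p": p,
        "fdr": fdr,
        "direction": np.where(lfc >= 0, "up", "down"),
        "significant": (np.abs(lfc) > t) & (fdr < alpha),
    })
    return out


def one_vs_rest(x, labels, gene_names=None, contrast: str = "", **kwargs) -> pd.DataFrame:
    """Per-label one-vs-rest DE; one BH family per label, concatenated."""
    labels = np.asarray(labels)
    tables = []
    for lab in pd.unique(labels):
        idx_a = np.flatnonzero(labels == lab)
        idx_b = np.flatnonzero(labels != lab)
        if len(idx_b) == 0:
            continue
        tables.append(de_test(x, idx_a, idx_b, gene_names=gene_names,
                              group=str(lab), contrast=contrast, **kwargs))
    if not tables:
        raise ValueError("need at least two labels")
    return pd.concat(tables, ignore_index=True)
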