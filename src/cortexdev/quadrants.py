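"""SV/tDE scoring, quadrant assignment, enrichment and overlap statistics.

A gene's subclass-variability (SV) score is its maximum one-vs-rest
|log2 fold change| over subclasses at either age; its temporal (tDE) score
is its maximum |log2 fold change| between ages over subclasses. Both are
capped (default 2 on the log2 scale, matching the plotted axes). At a fold
threshold t = log2(threshold) the (SV, tDE) plane splits into quadrants:

    Q1 = subclass-specific temporal   (sv >= t, tde >= t)
    Q2 = global temporal              (sv <  t, tde >= t)
    Q3 = static non-specific          (sv <  t, tde <  t)
    Q4 = static subclass identity     (sv >= t, tde <  t)

Category enrichment per quadrant uses Fisher's exact test with Bonferroni
adjustment; cross-region overlap of temporally regulated gene lists uses
the hypergeometric upper tail, Bonferroni-corrected by the number of
subclasses tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import de_test, one_vs_rest

__all__ = [
    "sv_score",
    "tde_score",
    "assign_quadrants",
    "quadrant_analysis",
    "category_enrichment",
    "intersection_summary",
    "hypergeom_overlap",
]


def _max_abs_lfc(table: pd.DataFrame, cap: float) -> pd.Series:
    s = table.assign(a=table["log2fc"].abs()).groupby("gene")["a"].max()
    return s.clip(upper=cap)


def sv_score(marker_table: pd.DataFrame, cap: float = 2.0) -> pd.Series:
    """Subclass-variability score from one-vs-rest tables at both ages.

    ``marker_table`` must hold one-vs-rest contrasts per (subclass, age);
    the score is the capped maximum |log2fc| over all of them. Genes absent
    from the table (failing the expression filter everywhere) get no score.
    """
    if marker_table.empty:
        raise ValueError("empty marker table")
    if marker_table["contrast"].nunique() < 2:
        raise ValueError("marker_table must cover both timepoints")
    return _max_abs_lfc(marker_table, cap).rename("sv_score")


def tde_score(temporal_table: pd.DataFrame, cap: float = 2.0) -> pd.Series:
    """Temporal score: capped max per-subclass |log2fc| between the two ages."""
    if temporal_table.empty:
        raise ValueError("empty temporal table")
    return _max_abs_lfc(temporal_table, cap).rename("tde_score")


def assign_quadrants(scores: pd.DataFrame, fc_threshold: float = 2.0) -> pd.DataFrame:
    """Assign Q1-Q4 from columns ``sv_score``/``tde_score``.

    ``fc_threshold`` is a ratio; internally t = log2(threshold). Missing
    scores (gene never a candidate on one axis) count as 0.
    """
    t = np.log2(fc_threshold)
    out = scores.copy()
    sv = out["sv_score"].fillna(0.0).to_numpy()
    td = out["tde_score"].fillna(0.0).to_numpy()
    quad = np.where(sv >= t, np.where(td >= t, "Q1", "Q4"),
                    np.where(td >= t, "Q2", "Q3"))
    out["quadrant"] = quad
    return out


def quadrant_analysis(
    x,
    subclass_labels,
    timepoint_labels,
    gene_names=None,
    min_frac: float = 0.4,
    min_fc: float = 2.0,
    cap: float = 2.0,
    fc_threshold: float = 2.0,
    class_context: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full scoring for one neuronal class.

    Returns (quadrant table, one-vs-rest marker DE table, temporal DE
    table). The scored universe is the union of genes passing the
    expression filter in any (subclass, age) contrast.
    """
    subclass_labels = np.asarray(subclass_labels)
    timepoint_labels = np.asarray(timepoint_labels)
    tps = pd.unique(timepoint_labels)
    if len(tps) != 2:
        raise ValueError(f"need exactly two timepoints, got {list(tps)}")
    marker_tables = []
    for tp in tps:
        sel = np.flatnonzero(timepoint_labels == tp)
        tab = one_vs_rest(x[sel], subclass_labels[sel], gene_names=gene_names,
                          contrast=str(tp), min_frac=min_frac, min_fc=min_fc)
        marker_tables.append(tab)
    marker_table = pd.concat(marker_tables, ignore_index=True)

    temporal_tables = []
    t1, t2 = tps
    for s in pd.unique(subclass_labels):
        ia = np.flatnonzero((subclass_labels == s) & (timepoint_labels == t2))
        ib = np.flatnonzero((subclass_labels == s) & (timepoint_labels == t1))
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError(f"subclass {s} missing a timepoint")
        temporal_tables.append(de_test(x, ia, ib, gene_names=gene_names,
                                       group=str(s), contrast=f"{t2}-vs-{t1}",
                                       min_frac=min_frac, min_fc=min_fc))
    temporal_table = pd.concat(temporal_tables, ignore_index=True)

    sv = sv_score(marker_table, cap=cap)
    td = tde_score(temporal_table, cap=cap)
    scores = pd.concat([sv, td], axis=1)
    quad = assign_quadrants(scores, fc_threshold=fc_threshold)
    quad["class_context"] = class_context
    quad.index.name = "gene"
    return quad, marker_table, temporal_table


def category_enrichment(
    quadrants: pd.DataFrame,
    categories: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact enrichment of gene categories in each quadrant.

    ``categories`` has columns (gene, category); the universe is the scored
    genes. Per (quadrant, category) a 2x2 table over the universe is tested
    two-sided; odds ratios are sample ORs with a 0.5 Haldane correction
    when exactly one cell is zero (flagged); p_adj is Bonferroni over all
    quadrant x category tests; the call is enriched/depleted/neither per
    p_adj <= alpha and OR direction.
    """
    universe = pd.Index(quadrants.index)
    cats = categories[categories["gene"].isin(universe)]
    quads = ["Q1", "Q2", "Q3", "Q4"]
    cat_names = list(pd.unique(cats["category"]))
    n_tests = len(quads) * len(cat_names)
    rows = []
    for q in quads:
        in_q = set(quadrants.index[quadrants["quadrant"] == q])
        for c in cat_names:
            in_c = set(cats.loc[cats["category"] == c, "gene"])
            a = len(in_q & in_c)
            b = len(in_q) - a
            cc = len(in_c) - a
            d = len(universe) - a - b - cc
            _, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
            zeros = sum(v == 0 for v in (a, b, cc, d))
            haldane = zeros == 1
            if zeros == 0:
                orr = (a * d) / (b * cc)
            elif haldane:
                orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (cc + 0.5))
            else:  # zero margin: sentinel, p still exact
                orr = np.inf if (b == 0 or cc == 0) else 0.0
            p_adj = min(1.0, p * n_tests)
            call = "neither"
            if p_adj <= alpha:
                call = "enriched" if orr > 1 else "depleted"
            rows.append({"quadrant": q, "category": c, "a": a, "b": b, "c": cc,
                         "d": d, "odds_ratio": orr, "haldane": haldane,
                         "p": p, "p_adj": p_adj, "call": call})
    return pd.DataFrame(rows)


def intersection_summary(de: pd.DataFrame, min_set: int = 4) -> dict:
    """Exclusive subclass-combination counts of significant genes (UpSet-style).

    ``de`` must be restricted to significant rows and carry columns
    (gene, group, direction). Each gene (per direction) is counted in
    exactly one exclusive combination of the subclasses it is regulated in.
    Combinations below ``min_set`` are suppressed from the displayed table
    but kept in the totals.
    """
    out: dict = {"directions": {}}
    n_up = n_down = 0
    for direction, sub in de.groupby("direction"):
        combos = sub.groupby("gene")["group"].apply(lambda g: tuple(sorted(set(g))))
        counts = combos.value_counts()
        total = int(counts.sum())
        specific = int(counts[[len(k) == 1 for k in counts.index]].sum())
        shown = counts[counts >= min_set]
        out["directions"][direction] = {
            "total_genes": total,
            "fraction_subclass_specific": specific / total if total else np.nan,
            "combinations_shown": {"+".join(k): int(v) for k, v in shown.items()},
            "combinations_suppressed": int((counts < min_set).sum()),
        }
        if direction == "up":
            n_up = total
        else:
            n_down = total
    out["down_up_ratio"] = n_down / n_up if n_up else np.inf
    return out


def hypergeom_overlap(list1, list2, universe, n_tests: int = 1,
                      label1: str = "", label2: str = "") -> dict:
    """Hypergeometric upper-tail test of two gene lists' overlap.

    With N = |universe|, K = |list1|, n = |list2|, k = |intersection|,
    p = P(X >= k) for X ~ Hypergeom(N, K, n); Bonferroni p_adj = min(1, p *
    n_tests). Symmetric in (list1, list2).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    s1, s2 = set(list1), set(list2)
    if not s1 <= universe or not s2 <= universe:
        raise ValueError("gene lists must be subsets of the universe")
    N, K, n = len(universe), len(s1), len(s2)
    k = len(s1 & s2)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return {"subclass_region1": label1, "subclass_region2": label2,
            "N": N, "K": K, "n": n, "k": k,
            "p": min(p, 1.0), "p_adj": min(1.0, p * n_tests)}
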