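"""Planted-truth recovery benchmarks.

Each function builds a synthetic dataset under the study conditions it
emulates, runs the corresponding analysis end to end, and returns measured
recovery/calibration numbers. They are the package's self-checks that the
statistical machinery recovers known answers, and they are what the
reproduction script reruns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scanpy as sc

from . import l23, mapping, qc, quadrants, simulate
from .de import de_test


def classifier_reference_design(seed: int, n_subclasses: int = 12,
                                cells_per_subclass: int = 1000,
                                n_genes: int = 2000,
                                n_markers: int = 50,
                                marker_effect: float = 2.0,
                                dispersion: float = 0.5) -> simulate.SimDesign:
    """Well-separated reference: 12 subclasses, 50 markers each at log2FC 2."""
    subclasses = [f"SC{i:02d}" for i in range(n_subclasses)]
    types_of = {s: [s + "_A"] for s in subclasses}
    cpt = pd.DataFrame(cells_per_subclass, index=[s + "_A" for s in subclasses],
                       columns=["T2"])
    d = simulate.SimDesign(
        conditions=["T2"], timepoint_of={"T2": "T2"}, subclasses=subclasses,
        class_of={s: "glutamatergic" for s in subclasses}, types_of=types_of,
        cells_per_type=cpt, n_genes=n_genes, dispersion=dispersion, seed=seed,
        marker_effect=marker_effect)
    d.programs = simulate.build_programs(
        d, n_q1_per_subclass=0, n_q2=0, n_hk=100,
        n_markers_per_subclass=n_markers, n_type_markers=0, n_ieg=0)
    d.validate()
    return d


def classifier_validation_benchmark(seed: int = 0) -> dict:
    """Held-out accuracy of the full train/validate protocol on the
    well-separated 12-subclass reference (the printed protocol-level bound
    is >=95%)."""
    design = classifier_reference_design(seed)
    adata, _ = simulate.simulate_counts(design)
    qc.compute_qc_metrics(adata)
    adata = qc.filter_genes(qc.filter_cells(adata), min_cells=100)
    adn = qc.normalize_log(adata)
    sc.pp.highly_variable_genes(adn, n_top_genes=min(2000, adn.n_vars - 1),
                                flavor="seurat")
    hvg = list(adn.var_names[adn.var["highly_variable"]])
    labels = adn.obs["subclass"].to_numpy()
    tr, ho, _ = mapping.split_train_validation(labels, frac=0.7, cap=1000,
                                               min_train=100, seed=seed)
    model = mapping.train_mapper(adn.X[tr], labels[tr], hvg,
                                 list(adn.var_names), seed=seed)
    acc, per_cluster, _ = mapping.validation_accuracy(
        model, adn.X, labels, list(adn.var_names), ho)
    return {"accuracy": float(acc), "n_heldout": int(len(ho)),
            "min_cluster_accuracy": float(per_cluster.min())}


def _context_truth(truth: simulate.GroundTruth, genes, class_subclasses) -> pd.Series:
    """Planted quadrant labels within one neuronal class's context: programs
    planted in the other class's subclasses are static/non-specific here."""
    tg = truth.genes
    out = []
    for g in genes:
        row = tg.loc[g]
        q = row["truth_quadrant"]
        if row["program"] in ("q1", "marker") and row["subclass"] not in class_subclasses:
            q = "Q3"
        out.append(q)
    return pd.Series(out, index=genes)


def quadrant_recovery_benchmark(seed: int = 0, cells_per_subclass: int = 1000,
                                n_genes: int = 1200) -> dict:
    """Recovery of planted Q1-Q4 programs at ~1,000 cells/subclass/condition,
    plus the fold-threshold robustness sweep."""
    design = simulate.default_design(
        cells_per_type=0, n_genes=n_genes, seed=seed, conditions=["P12", "P22"],
        continuum=False, frequency_spread=1.0,
        program_kwargs={"n_type_markers": 0, "n_continuum_markers": 0})
    for s in design.subclasses:
        tys = design.types_of[s]
        for t in tys:
            design.cells_per_type.loc[t] = int(round(cells_per_subclass / len(tys)))
    adata, truth = simulate.simulate_counts(design)
    qc.compute_qc_metrics(adata)
    adn = qc.normalize_log(qc.filter_cells(adata))
    cond = adn.obs["condition"].to_numpy()
    tp = np.where(cond == "P12", "T1", "T2")
    genes = np.array(adn.var_names)

    out: dict = {"per_class": {}, "sweep_q1_recall": {}}
    for cls in ("glutamatergic", "GABAergic"):
        sel = (adn.obs["class"] == cls).to_numpy()
        quad, _, _ = quadrants.quadrant_analysis(
            adn.X[sel], adn.obs["subclass"].to_numpy()[sel], tp[sel],
            gene_names=genes, class_context=cls)
        cls_subs = [s for s in design.subclasses if design.class_of[s] == cls]
        tq = _context_truth(truth, quad.index, cls_subs)
        metrics = {}
        for q in ("Q1", "Q2", "Q3", "Q4"):
            hit = ((quad["quadrant"] == q) & (tq == q)).sum()
            metrics[q] = {
                "precision": hit / max((quad["quadrant"] == q).sum(), 1),
                "recall": hit / max((tq == q).sum(), 1),
            }
        out["per_class"][cls] = metrics
        if cls == "glutamatergic":
            q1_genes = [g for g in quad.index
                        if truth.genes.loc[g, "program"] == "q1"
                        and truth.genes.loc[g, "subclass"] in cls_subs]
            for fc in (1.5, 2.0, 2.5):
                sweep = quadrants.assign_quadrants(
                    quad[["sv_score", "tde_score"]], fc_threshold=fc)
                out["sweep_q1_recall"][fc] = float(
                    (sweep.loc[q1_genes, "quadrant"] == "Q1").mean())
    return out


def _shift_fixture(seed: int, cells_per_type: int = 333, n_genes: int = 1000):
    design = simulate.default_design(cells_per_type=cells_per_type,
                                     n_genes=n_genes, seed=seed,
                                     conditions=["P12", "P22"],
                                     frequency_spread=1.0)
    adata, truth = simulate.simulate_counts(design)
    qc.compute_qc_metrics(adata)
    adn = qc.normalize_log(qc.filter_cells(adata))
    return design, adn, truth


def shift_specificity_benchmark(seed: int = 0, n_repeats: int = 20,
                                flag_fold: float = 1.5,
                                alpha: float = 0.01) -> dict:
    """Specificity of compositional-shift detection over repeats.

    Per repeat: only the continuum subclass's type frequencies differ
    between ages (A halved, B doubled, C stable). Success = the frequency
    table flags exactly those two types, and the family-wise Bonferroni
    KS screen over all subclasses is significant only for that subclass.
    """
    successes = 0
    details = []
    for rep in range(n_repeats):
        design, adn, truth = _shift_fixture(seed * 1000 + rep)
        cond = adn.obs["condition"].to_numpy()
        types = truth.cells.loc[adn.obs_names, "type"].to_numpy()
        genes = np.array(adn.var_names)
        sel_g = (adn.obs["class"] == "glutamatergic").to_numpy()
        table, _ = mapping.frequency_concordance(types[sel_g & (cond == "P12")],
                                                 types[sel_g & (cond == "P22")])
        flagged = set(table.index[np.abs(table["log2_ratio"]) > np.log2(flag_fold)])
        pvals = []
        for s in design.subclasses:
            sels = (adn.obs["subclass"] == s).to_numpy()
            x = adn.X[sels]
            ty = types[sels]
            cd = cond[sels]
            ref = cd == "P22"
            m = l23.select_type_markers(x[ref], ty[ref], genes)
            scores = {t: l23.marker_score(x, genes, m[t])
                      for t in m if t != "union" and m[t]}
            emb = l23.pca_condition(x, genes, m["union"], n_components=2)
            _, ks = l23.pc1_profile(scores, emb.scores[:, 0], cd)
            pvals.extend((s, p) for p in ks["p"])
        n_tests = len(pvals)
        sig = {s for s, p in pvals if min(1.0, p * n_tests) < alpha}
        ok = flagged == {"L23_A", "L23_B"} and sig == {"L23"}
        successes += ok
        details.append({"flagged": sorted(flagged), "significant": sorted(sig)})
    return {"success_fraction": successes / n_repeats, "n_repeats": n_repeats,
            "details": details}


def correspondence_benchmark(seed: int = 0, cells_per_type: int = 400,
                             n_genes: int = 1000) -> dict:
    """Eigenvector correspondence of two fixtures from one generative model:
    |dot| of the top-2 loadings should be diagonal-dominant."""
    def make(s):
        design = simulate.default_design(cells_per_type=0, n_genes=n_genes,
                                         seed=s, conditions=["P12", "P22"])
        for t in design.types_of["L23"]:
            design.cells_per_type.loc[t] = cells_per_type
        adata, _ = simulate.simulate_counts(design)
        qc.compute_qc_metrics(adata)
        return qc.normalize_log(qc.filter_cells(adata))

    a1, a2 = make(seed * 100 + 1), make(seed * 100 + 2)
    genes = np.array(a1.var_names)
    sel1 = (a1.obs["subclass"] == "L23").to_numpy()
    sel2 = (a2.obs["subclass"] == "L23").to_numpy()
    ref = sel1 & (a1.obs["condition"] == "P22").to_numpy()
    m = l23.select_type_markers(a1.X[ref], a1.obs["type"].to_numpy()[ref], genes)
    e1 = l23.pca_condition(a1.X[sel1], genes, m["union"], n_components=2)
    e2 = l23.pca_condition(a2.X[sel2], genes, m["union"], n_components=2)
    M, one_to_one = l23.eigenvector_correspondence(e1, e2, n=2)
    return {"diag_min": float(np.diag(M).min()),
            "offdiag_max": float((M - np.diag(np.diag(M))).max()),
            "one_to_one": bool(one_to_one)}


def null_calibration_benchmark(seed: int = 0, n_seeds: int = 20,
                               n_genes: int = 2000,
                               cells_per_group: int = 250) -> dict:
    """False-positive rate of the DE test on exchangeable nulls, and the
    KS test's rejection rate at alpha=0.05."""
    fprs = []
    for rep in range(n_seeds):
        design = simulate.default_design(
            cells_per_type=0, n_genes=n_genes, seed=seed * 1000 + rep,
            conditions=["T1", "T2"], continuum=False,
            program_kwargs={"n_q1_per_subclass": 0, "n_q2": 0, "n_hk": 900,
                            "n_markers_per_subclass": 0, "n_type_markers": 0,
                            "n_ieg": 0})
        for t in design.types_of["L4"]:
            design.cells_per_type.loc[t] = cells_per_group // len(design.types_of["L4"])
        adata, _ = simulate.simulate_counts(design)
        qc.compute_qc_metrics(adata)
        adn = qc.normalize_log(qc.filter_cells(adata))
        cond = adn.obs["condition"].to_numpy()
        tab = de_test(adn.X, np.flatnonzero(cond == "T1"),
                      np.flatnonzero(cond == "T2"), min_frac=0.4, min_fc=2.0)
        fprs.append(float((tab["fdr"] < 0.05).mean()))

    rng = np.random.default_rng(seed)
    rejections = 0
    n_ks = 100
    for _ in range(n_ks):
        a, b = rng.normal(size=(2, 500))
        _, p = l23.ks_compare(a, b)
        rejections += p < 0.05
    return {"de_fpr_mean": float(np.mean(fprs)), "de_fpr_max": float(np.max(fprs)),
            "ks_rejection_rate": rejections / n_ks, "n_seeds": n_seeds}
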