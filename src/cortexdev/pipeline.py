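"""End-to-end orchestration: simulate -> QC -> quadrants -> label transfer
-> continuum analysis -> cross-region overlap, with a JSON run manifest.

Outputs are plain TSV/JSON for auditability; matrices are Matrix Market.
Every threshold used and every removal count appears in the manifest, and a
rerun with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, l23, mapping, qc, quadrants, simulate


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending field(s)."""


DEFAULTS = {
    "seed": 0,
    "simulate": {"cells_per_type": 40, "n_genes": 1000, "doublet_rate": 0.02,
                 "lowq_rate": 0.03, "himito_rate": 0.03,
                 "frequency_spread": 10.0},
    "qc": {"max_genes": 7000, "max_counts": 40000, "min_counts": 500,
           "min_cells_per_gene": 20, "mito_cluster_threshold": 0.2,
           "n_hvg": 500, "n_pcs": 40, "k_neighbors": 15, "resolution": 1.0,
           "target_sum": 10000.0},
    "quadrants": {"min_frac": 0.4, "min_fc": 2.0, "cap": 2.0, "fc_threshold": 2.0},
    "map": {"reject_factor": 1.2, "frac": 0.7, "cap": 1000, "min_train": 100},
    "l23": {"min_fc": 1.5, "min_frac": 0.2, "n_components": 2},
    "overlap": {"region2_seed": None},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_dict)
    merged = {}
    for key, block in DEFAULTS.items():
        if isinstance(block, dict):
            merged[key] = dict(block)
            user = cfg.get(key, {})
            if not isinstance(user, dict):
                raise ConfigError(f"{key}: expected a mapping")
            unknown = set(user) - set(block)
            if unknown:
                raise ConfigError(f"{key}.{sorted(unknown)[0]}: unknown field")
            merged[key].update(user)
        else:
            merged[key] = cfg.get(key, block)
    for extra in set(cfg) - set(DEFAULTS) - {"input_dir"}:
        raise ConfigError(f"{extra}: unknown section")
    if "input_dir" in cfg:
        merged["input_dir"] = cfg["input_dir"]
    _validate(merged)
    return merged


def _validate(cfg: dict) -> None:
    q = cfg["qc"]
    if q["min_counts"] >= q["max_counts"]:
        raise ConfigError("qc.min_counts, qc.max_counts: min_counts must be "
                          f"< max_counts (got {q['min_counts']} >= {q['max_counts']})")
    for f in ("max_genes", "max_counts", "min_counts", "min_cells_per_gene"):
        if q[f] <= 0:
            raise ConfigError(f"qc.{f}: must be positive")
    if not (0 < cfg["map"]["frac"] < 1):
        raise ConfigError("map.frac: must be in (0,1)")
    if cfg["quadrants"]["min_fc"] <= 1:
        raise ConfigError("quadrants.min_fc: fold-change ratio must exceed 1")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed: must be an integer")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index)


def synthetic_categories(truth: simulate.GroundTruth, seed: int) -> pd.DataFrame:
    """Gene-category table (TF/CAM/IC/HK) for the planted fixture.

    HK is the planted housekeeping program; CAM/IC draw preferentially from
    subclass-specific programs (as adhesion molecules and channels do in
    cortex); TF is sampled broadly.
    """
    rng = np.random.default_rng(seed + 101)
    g = truth.genes
    rows = []
    hk = g.index[g["program"] == "hk"]
    rows += [(x, "HK") for x in hk]
    specific = list(g.index[g["program"].isin(["q1", "marker"])])
    rng.shuffle(specific)
    half = len(specific) // 2
    rows += [(x, "CAM") for x in specific[:half]]
    rows += [(x, "IC") for x in specific[half:]]
    tf = rng.choice(g.index, size=min(60, len(g)), replace=False)
    rows += [(x, "TF") for x in tf]
    return pd.DataFrame(rows, columns=["gene", "category"]).drop_duplicates("gene")


def run_pipeline(config, outdir: str | Path) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    A stage failure leaves completed-stage outputs in place and records the
    error in the manifest before re-raising.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest: dict = {"version": __version__, "config": cfg, "stages": {}}

    def finish(stage, info):
        manifest["stages"][stage] = info
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str, sort_keys=True)

    try:
        # ---- simulate / load
        if "input_dir" in cfg:
            adata, truth = simulate.read_fixture(cfg["input_dir"])
            finish("simulate", {"loaded": str(cfg["input_dir"]), "cells": adata.n_obs})
        else:
            sim = cfg["simulate"]
            design = simulate.default_design(seed=seed, **sim)
            adata, truth = simulate.simulate_counts(design)
            fixdir = outdir / "fixture"
            simulate.write_fixture(adata, truth, fixdir, overwrite=True)
            cats = synthetic_categories(truth, seed)
            _write(cats, outdir / "categories.tsv")
            finish("simulate", {"cells": adata.n_obs, "genes": adata.n_vars,
                                "fixture": str(fixdir),
                                "design": simulate.design_manifest(design)})

        # ---- QC
        qcfg = cfg["qc"]
        qc.compute_qc_metrics(adata)
        n0 = adata.n_obs
        adata = qc.filter_cells(adata, qcfg["max_genes"], qcfg["max_counts"],
                                qcfg["min_counts"])
        n1 = adata.n_obs
        adata = qc.filter_genes(adata, qcfg["min_cells_per_gene"])
        adn = qc.normalize_log(adata, target_sum=qcfg["target_sum"])
        clusters = qc.cluster_pipeline(adn, n_hvg=qcfg["n_hvg"], n_pcs=qcfg["n_pcs"],
                                       k_neighbors=qcfg["k_neighbors"],
                                       resolution=qcfg["resolution"], seed=seed)
        adn, labels = qc.remove_mito_clusters(adn, clusters,
                                              qcfg["mito_cluster_threshold"])
        cells_out = adn.obs.copy()
        cells_out["cluster"] = labels
        _write(cells_out.reset_index(), outdir / "qc_cells.tsv")
        finish("qc", {"thresholds": qcfg, "cells_in": n0,
                      "cells_after_cell_filter": n1,
                      "genes_after_gene_filter": adn.n_vars,
                      "cells_after_mito_clusters": adn.n_obs,
                      "n_clusters": int(len(np.unique(clusters.labels)))})

        genes = np.array(adn.var_names)
        cond = adn.obs["condition"].to_numpy()
        conditions = list(pd.unique(cond))
        t1_cond = conditions[0]
        ref_cond = conditions[1] if len(conditions) > 1 else conditions[0]

        # ---- quadrants + enrichment (two control conditions, per class)
        qq = cfg["quadrants"]
        sel_tc = np.isin(cond, [t1_cond, ref_cond])
        tp = np.where(cond == t1_cond, "T1", "T2")
        quad_tables, temporal_tables = [], []
        for cls in pd.unique(adn.obs["class"]):
            sel = sel_tc & (adn.obs["class"] == cls).to_numpy()
            quad, _, temporal = quadrants.quadrant_analysis(
                adn.X[sel], adn.obs["subclass"].to_numpy()[sel], tp[sel],
                gene_names=genes, min_frac=qq["min_frac"], min_fc=qq["min_fc"],
                cap=qq["cap"], fc_threshold=qq["fc_threshold"], class_context=str(cls))
            quad_tables.append(quad.reset_index())
            temporal_tables.append(temporal.assign(class_context=str(cls)))
        quad_all = pd.concat(quad_tables, ignore_index=True)
        temporal_all = pd.concat(temporal_tables, ignore_index=True)
        _write(quad_all, outdir / "quadrants.tsv")
        _write(temporal_all, outdir / "de_temporal.tsv")
        cats_path = outdir / "categories.tsv"
        if cats_path.exists():
            cats = pd.read_csv(cats_path, sep="\t")
            first = quad_all[quad_all["class_context"] == quad_all["class_context"].iloc[0]]
            enr = quadrants.category_enrichment(first.set_index("gene"), cats)
            _write(enr, outdir / "enrichment.tsv")
        sig = temporal_all[temporal_all["significant"]]
        inter = quadrants.intersection_summary(sig) if len(sig) else {}
        with open(outdir / "intersections.json", "w") as fh:
            json.dump(inter, fh, indent=1)
        finish("quadrants", {"params": qq,
                             "quadrant_sizes": quad_all["quadrant"].value_counts().to_dict(),
                             "n_temporal_significant": int(sig["gene"].nunique())})

        # ---- label transfer: reference condition -> each other condition
        mcfg = cfg["map"]
        ref_sel = np.flatnonzero(cond == ref_cond)
        labels_ref = adn.obs["subclass"].to_numpy()[ref_sel]
        tr, ho, split_man = mapping.split_train_validation(
            labels_ref, frac=mcfg["frac"], cap=mcfg["cap"],
            min_train=mcfg["min_train"], seed=seed)
        model = mapping.train_mapper(adn.X[ref_sel][tr], labels_ref[tr],
                                     list(genes), list(genes), seed=seed)
        acc, per_cluster, _ = mapping.validation_accuracy(
            model, adn.X[ref_sel], labels_ref, list(genes), ho,
            reject_factor=mcfg["reject_factor"])
        map_rows, conc = [], {}
        for c in conditions:
            if c == ref_cond:
                continue
            sel = np.flatnonzero(cond == c)
            res = mapping.predict_labels(model, adn.X[sel], list(genes),
                                         cell_names=adn.obs_names[sel],
                                         reject_factor=mcfg["reject_factor"])
            map_rows.append(pd.DataFrame({"barcode": adn.obs_names[sel],
                                          "condition": c,
                                          "assigned": res.assigned.to_numpy(),
                                          "max_prob": res.max_prob.to_numpy()}))
            try:
                _, r = mapping.frequency_concordance(
                    res.assigned[res.assigned != "Unassigned"], labels_ref)
                conc[c] = r
            except ValueError:
                conc[c] = None
        if map_rows:
            _write(pd.concat(map_rows, ignore_index=True), outdir / "mapping.tsv")
        finish("map", {"params": mcfg, "validation_accuracy": acc,
                       "split": split_man, "frequency_concordance": conc})

        # ---- continuum (L2/3-style) analysis
        lcfg = cfg["l23"]
        cont = "L23" if "L23" in set(adn.obs["subclass"]) else None
        markers = None
        if cont is None or "type" not in adn.obs:
            finish("l23", {"skipped": "no continuum subclass present"})
        else:
            sel = (adn.obs["subclass"] == cont).to_numpy()
            x = adn.X[sel]
            ty = adn.obs["type"].to_numpy()[sel]
            cd = cond[sel]
            ref = cd == ref_cond
            try:
                markers = l23.select_type_markers(x[ref], ty[ref], genes,
                                                  min_fc=lcfg["min_fc"],
                                                  min_frac=lcfg["min_frac"])
            except ValueError as err:
                finish("l23", {"skipped": str(err)})
        if markers is not None:
            union = markers["union"]
            embeds = {c: l23.pca_condition(x[cd == c], genes, union,
                                           n_components=lcfg["n_components"])
                      for c in conditions if (cd == c).sum() >= lcfg["n_components"]}
            corr_rows = []
            for c, e in embeds.items():
                if c == ref_cond:
                    continue
                M, oto = l23.eigenvector_correspondence(embeds[ref_cond], e,
                                                        n=lcfg["n_components"])
                corr_rows.append({"condition": c, "diag_min": float(np.diag(M).min()),
                                  "offdiag_max": float((M - np.diag(np.diag(M))).max()),
                                  "one_to_one": oto})
            scores = {t: l23.marker_score(x, genes, markers[t])
                      for t in markers if t != "union" and markers[t]}
            e_all = l23.pca_condition(x, genes, union, n_components=lcfg["n_components"])
            curves, ks = l23.pc1_profile(scores, e_all.scores[:, 0], cd)
            _write(ks, outdir / "l23_ks.tsv")
            _write(pd.DataFrame(corr_rows), outdir / "l23_correspondence.tsv")
            finish("l23", {"n_markers": len(union),
                           "correspondence": corr_rows,
                           "min_ks_p_adj": float(ks["p_adj"].min())})

        # ---- cross-region overlap of temporal gene lists
        ocfg = cfg["overlap"]
        if ocfg["region2_seed"] is not None and "input_dir" not in cfg:
            sim = cfg["simulate"]
            design2 = simulate.default_design(seed=int(ocfg["region2_seed"]), **sim)
            a2, _ = simulate.simulate_counts(design2)
            qc.compute_qc_metrics(a2)
            a2 = qc.filter_genes(qc.filter_cells(a2), qcfg["min_cells_per_gene"])
            a2 = qc.normalize_log(a2, target_sum=qcfg["target_sum"])
            rows = []
            g2 = np.array(a2.var_names)
            cond2 = a2.obs["condition"].to_numpy()
            tp2 = np.where(cond2 == t1_cond, "T1", "T2")
            sel2 = np.isin(cond2, [t1_cond, ref_cond])
            subs = sorted(set(adn.obs["subclass"]) & set(a2.obs["subclass"]))
            for direction in ("up", "down"):
                lists1, lists2 = {}, {}
                for s in subs:
                    m1 = sig[(sig["group"] == s) & (sig["direction"] == direction)]
                    lists1[s] = set(m1["gene"])
                for s in subs:
                    s_sel = sel2 & (a2.obs["subclass"] == s).to_numpy()
                    ia = np.flatnonzero(s_sel & (tp2 == "T2"))
                    ib = np.flatnonzero(s_sel & (tp2 == "T1"))
                    from .de import de_test
                    t2 = de_test(a2.X, ia, ib, gene_names=g2,
                                 min_frac=qq["min_frac"], min_fc=qq["min_fc"])
                    t2 = t2[t2["significant"]]
                    lists2[s] = set(t2.loc[t2["direction"] == direction, "gene"])
                universe = set().union(*lists1.values()) | set().union(*lists2.values())
                tested = [s for s in subs if lists1[s] and lists2[s]]
                for s in tested:
                    r = quadrants.hypergeom_overlap(
                        lists1[s] & universe, lists2[s] & universe, universe,
                        n_tests=len(tested), label1=s, label2=s)
                    r["direction"] = direction
                    rows.append(r)
            overlap_df = pd.DataFrame(rows)
            _write(overlap_df, outdir / "overlap.tsv")
            finish("overlap", {"n_tests": len(rows),
                               "n_significant": int((overlap_df["p_adj"] < 0.05).sum())
                               if len(rows) else 0})
        else:
            finish("overlap", {"skipped": "no region2_seed configured"})
    except Exception as err:  # record, keep completed stages, re-raise
        finish("error", {"message": str(err)})
        raise

    # file hashes for provenance
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str, sort_keys=True)
    return manifest


def report(outputs_dir: str | Path) -> dict:
    """Aggregate stage TSVs/manifest into one machine-readable summary."""
    outputs_dir = Path(outputs_dir)
    out: dict = {"incomplete": []}
    man_path = outputs_dir / "manifest.json"
    if man_path.exists():
        with open(man_path) as fh:
            man = json.load(fh)
        out["stages_run"] = sorted(man.get("stages", {}))
        stages = man.get("stages", {})
        if "map" in stages and "validation_accuracy" in stages["map"]:
            out["mapping_accuracy"] = stages["map"]["validation_accuracy"]
            out["frequency_concordance"] = stages["map"].get("frequency_concordance")
    else:
        out["incomplete"].append("manifest.json")
    quad_path = outputs_dir / "quadrants.tsv"
    if quad_path.exists():
        quad = pd.read_csv(quad_path, sep="\t")
        out["quadrant_sizes"] = quad["quadrant"].value_counts().to_dict()
        out["n_scored_genes"] = int(len(quad))
    else:
        out["incomplete"].append("quadrants.tsv")
    enr_path = outputs_dir / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        out["enrichment_calls"] = enr.groupby("call").size().to_dict()
    else:
        out["incomplete"].append("enrichment.tsv")
    ks_path = outputs_dir / "l23_ks.tsv"
    if ks_path.exists():
        ks = pd.read_csv(ks_path, sep="\t")
        out["l23_min_ks_p_adj"] = float(ks["p_adj"].min())
    else:
        out["incomplete"].append("l23_ks.tsv")
    with open(outputs_dir / "report.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out
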