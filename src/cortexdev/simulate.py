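"""Synthetic snRNA-seq data with planted ground truth.

Emulates the statistical structure of a developing-cortex single-nucleus
atlas: a class/subclass/type taxonomy sampled at two ages plus perturbation
conditions, with four planted gene programs

* subclass-specific temporal genes (quadrant Q1),
* globally temporal genes (Q2),
* static housekeeping genes (Q3),
* static subclass markers (Q4),

a three-type continuum subclass whose type composition shifts between ages,
immediate-early-gene induction in one perturbation condition, and the
artifacts a QC pipeline must remove (low-library cells, high-mitochondrial
cells, doublets).

Counts are drawn gene-wise from a negative binomial (Gamma-Poisson) with

    mean = baseline * 2^(sum of applicable planted log2 effects) * size factor

and variance mu + mu^2/theta, where theta is the per-gene inverse
dispersion. All randomness flows from a single seeded generator, so a fixed
seed yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SimDesign",
    "GroundTruth",
    "default_design",
    "simulate_counts",
    "write_fixture",
    "read_fixture",
]


@dataclass
class SimDesign:
    """Full specification of a simulated dataset.

    ``cells_per_type`` is a (type x condition) integer table. For the
    continuum subclass the per-type rows are interpreted as a per-subclass
    total; realised type labels follow ``composition`` via the latent
    coordinate (see :func:`simulate_counts`).
    """

    conditions: list[str]
    timepoint_of: dict[str, str]          # condition -> "T1" | "T2"
    subclasses: list[str]
    class_of: dict[str, str]              # subclass -> class label
    types_of: dict[str, list[str]]        # subclass -> type names
    cells_per_type: pd.DataFrame          # index: type, columns: condition
    n_genes: int = 2000
    n_mito_genes: int = 13
    programs: pd.DataFrame | None = None  # per-gene program table (built if None)
    continuum_subclass: str | None = None
    composition: pd.DataFrame | None = None  # continuum type freqs, index=type, cols=condition
    dispersion: float | np.ndarray = 0.5  # NB inverse dispersion theta
    library_size_lognormal: tuple[float, float] = (0.0, 0.35)
    mito_fraction: float = 0.05
    doublet_rate: float = 0.0
    lowq_rate: float = 0.0
    himito_rate: float = 0.0
    n_replicates: int = 2
    seed: int = 0
    # planted effect sizes (log2) used when programs is built internally
    marker_effect: float = 2.0
    temporal_effect: float = 2.0
    pert_effect: float = 2.0
    type_marker_effect: float = 2.0

    def validate(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels not unique")
        if np.any(np.asarray(self.dispersion, dtype=float) <= 0):
            raise ValueError("dispersion must be positive")
        if (self.cells_per_type.to_numpy() < 0).any():
            raise ValueError("cells_per_type entries must be >= 0")
        missing = set(self.conditions) - set(self.timepoint_of)
        if missing:
            raise ValueError(f"conditions missing a timepoint: {sorted(missing)}")
        if self.composition is not None:
            sums = self.composition.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("composition frequency vectors must sum to 1")
        if self.continuum_subclass is not None and self.composition is None:
            raise ValueError("continuum subclass requires a composition table")

    @property
    def all_types(self) -> list[str]:
        return [t for s in self.subclasses for t in self.types_of[s]]

    def subclass_of_type(self) -> dict[str, str]:
        return {t: s for s in self.subclasses for t in self.types_of[s]}


@dataclass
class GroundTruth:
    """Planted truth for every cell and gene of a simulated dataset."""

    cells: pd.DataFrame       # class/subclass/type, is_doublet, is_lowq, is_himito, u
    genes: pd.DataFrame       # program, truth_quadrant, effect columns
    type_freqs: pd.DataFrame  # designed type frequency vectors per condition


# ---------------------------------------------------------------------------
# default design: 2 classes / 12 subclasses / 45 types, 4 conditions

_GLUT = ["L23", "L4", "L5IT", "L5PT", "L5NP", "L6CT", "L6IT", "L6b"]
_GABA = ["Pvalb", "Sst", "Vip", "Lamp5"]
_N_TYPES = {"L23": 3, "L4": 4, "L5IT": 4, "L5PT": 4, "L5NP": 3, "L6CT": 4,
            "L6IT": 4, "L6b": 3, "Pvalb": 4, "Sst": 4, "Vip": 4, "Lamp5": 4}


def default_design(
    cells_per_type: int = 40,
    n_genes: int = 2000,
    conditions: list[str] | None = None,
    doublet_rate: float = 0.0,
    lowq_rate: float = 0.0,
    himito_rate: float = 0.0,
    continuum: bool = True,
    frequency_spread: float = 10.0,
    seed: int = 0,
    program_kwargs: dict | None = None,
    **overrides,
) -> SimDesign:
    """Design emulating the study: 12 subclasses / 45 types, two ages and
    two whisker-deprivation conditions, with all planted programs.

    ``cells_per_type`` is the mean; realized per-type counts follow a
    deterministic log spread over ``frequency_spread`` (relative abundance
    of the commonest to the rarest type), stable across conditions, since
    real type frequencies span orders of magnitude. Set
    ``frequency_spread=1`` for uniform types.
    """
    if conditions is None:
        conditions = ["P12", "P22", "P22_AWD", "P22_RWD"]
    timepoint_of = {c: ("T1" if c == conditions[0] else "T2") for c in conditions}
    subclasses = _GLUT + _GABA
    class_of = {s: ("glutamatergic" if s in _GLUT else "GABAergic") for s in subclasses}
    types_of = {s: [f"{s}_{chr(65 + i)}" for i in range(_N_TYPES[s])] for s in subclasses}
    all_types = [t for s in subclasses for t in types_of[s]]
    T = len(all_types)
    w = np.geomspace(1.0, 1.0 / max(frequency_spread, 1.0), T)
    w = np.random.default_rng(seed + 13).permutation(w)
    w *= T / w.sum()
    counts = np.maximum(1, np.round(cells_per_type * w)).astype(int) \
        if cells_per_type > 0 else np.zeros(T, dtype=int)
    cpt = pd.DataFrame({c: counts for c in conditions}, index=all_types, dtype=int)

    composition = None
    continuum_subclass = None
    if continuum:
        continuum_subclass = "L23"
        composition = pd.DataFrame(index=types_of["L23"], columns=conditions, dtype=float)
        for c in conditions:
            # type A halves and B doubles between the two ages; C is stable
            composition[c] = [0.5, 0.2, 0.3] if timepoint_of[c] == "T1" else [0.25, 0.4, 0.35]

    design = SimDesign(
        conditions=conditions,
        timepoint_of=timepoint_of,
        subclasses=subclasses,
        class_of=class_of,
        types_of=types_of,
        cells_per_type=cpt,
        n_genes=n_genes,
        continuum_subclass=continuum_subclass,
        composition=composition,
        doublet_rate=doublet_rate,
        lowq_rate=lowq_rate,
        himito_rate=himito_rate,
        seed=seed,
        **overrides,
    )
    design.programs = build_programs(design, **(program_kwargs or {}))
    design.validate()
    return design


def build_programs(
    design: SimDesign,
    n_q1_per_subclass: int = 5,
    n_q2: int = 40,
    n_hk: int = 100,
    n_markers_per_subclass: int = 20,
    n_type_markers: int = 8,
    n_continuum_markers: int = 30,
    n_ieg: int = 10,
    baseline_program: float = 3.0,
    baseline_hk: float = 8.0,
) -> pd.DataFrame:
    """Lay out gene programs deterministically over the gene index.

    Returns a per-gene table with columns: program, subclass (for Q1/Q4),
    type (for type markers), effect (log2), baseline, is_mito,
    truth_quadrant. Genes not assigned to any program are low-expressed
    background (truth Q3, mostly below the expression filter).
    """
    rng = np.random.default_rng(design.seed + 7)
    n = design.n_genes
    prog = pd.DataFrame({
        "program": np.array(["background"] * n, dtype=object),
        "subclass": np.array([""] * n, dtype=object),
        "type": np.array([""] * n, dtype=object),
        "effect": np.zeros(n),
        "baseline": np.zeros(n),
        "is_mito": np.zeros(n, dtype=bool),
    })
    cursor = 0

    def take(k):
        nonlocal cursor
        idx = np.arange(cursor, cursor + k)
        if cursor + k > n:
            raise ValueError("n_genes too small for requested programs")
        cursor += k
        return idx

    mito_idx = take(design.n_mito_genes)
    prog.loc[mito_idx, "program"] = "mito"
    prog.loc[mito_idx, "is_mito"] = True

    sign = 1.0
    for s in design.subclasses:
        idx = take(n_q1_per_subclass)
        prog.loc[idx, "program"] = "q1"
        prog.loc[idx, "subclass"] = s
        # alternate induction / repression at the older age
        eff = np.full(len(idx), design.temporal_effect)
        eff[1::2] *= -1
        prog.loc[idx, "effect"] = sign * eff
        sign *= -1.0

    idx = take(n_q2)
    prog.loc[idx, "program"] = "q2"
    eff = np.full(len(idx), design.temporal_effect)
    eff[1::2] *= -1
    prog.loc[idx, "effect"] = eff

    idx = take(n_hk)
    prog.loc[idx, "program"] = "hk"

    for s in design.subclasses:
        idx = take(n_markers_per_subclass)
        prog.loc[idx, "program"] = "marker"
        prog.loc[idx, "subclass"] = s
        prog.loc[idx, "effect"] = design.marker_effect

    if design.continuum_subclass is not None:
        for t in design.types_of[design.continuum_subclass]:
            idx = take(n_continuum_markers)
            prog.loc[idx, "program"] = "type_marker"
            prog.loc[idx, "subclass"] = design.continuum_subclass
            prog.loc[idx, "type"] = t
            prog.loc[idx, "effect"] = design.type_marker_effect
    for s in design.subclasses:
        if s == design.continuum_subclass:
            continue
        for t in design.types_of[s]:
            idx = take(n_type_markers)
            prog.loc[idx, "program"] = "type_marker"
            prog.loc[idx, "subclass"] = s
            prog.loc[idx, "type"] = t
            prog.loc[idx, "effect"] = design.type_marker_effect

    idx = take(n_ieg)
    prog.loc[idx, "program"] = "ieg"
    prog.loc[idx, "effect"] = design.pert_effect

    # baselines: planted programs expressed well above the detection filter,
    # housekeeping higher, background mostly low (below the 40% filter)
    planted = prog["program"].isin(["q1", "q2", "marker", "type_marker", "ieg"])
    prog.loc[planted, "baseline"] = baseline_program * rng.lognormal(0.0, 0.25, planted.sum())
    # temporally down-regulated genes start high (like developmental genes
    # switched off during maturation); this also balances library totals
    # across ages so that planted static genes stay static after
    # library-size normalization
    down = prog["program"].isin(["q1", "q2"]) & (prog["effect"] < 0)
    prog.loc[down, "baseline"] *= np.exp2(-prog.loc[down, "effect"])
    hk = prog["program"] == "hk"
    prog.loc[hk, "baseline"] = baseline_hk * rng.lognormal(0.0, 0.25, hk.sum())
    bg = prog["program"] == "background"
    prog.loc[bg, "baseline"] = rng.lognormal(-1.8, 1.2, bg.sum())
    # mito baselines set to hit the designed mitochondrial fraction
    non_mito_total = prog.loc[~prog["is_mito"], "baseline"].sum()
    f = design.mito_fraction
    mito_total = non_mito_total * f / (1.0 - f)
    w = rng.dirichlet(np.full(design.n_mito_genes, 5.0))
    prog.loc[mito_idx, "baseline"] = mito_total * w

    quad = {"q1": "Q1", "q2": "Q2", "hk": "Q3", "background": "Q3",
            "marker": "Q4", "mito": "Q3", "ieg": "Q3", "type_marker": ""}
    prog["truth_quadrant"] = prog["program"].map(quad)
    return prog


# ---------------------------------------------------------------------------
# simulation


def _continuum_memberships(u: np.ndarray) -> np.ndarray:
    """Triangular hat memberships of the three continuum types along u in [0,1]."""
    centers = np.array([0.0, 0.5, 1.0])
    w = np.clip(1.0 - np.abs(u[:, None] - centers[None, :]) / 0.5, 0.0, None)
    return w / w.sum(axis=1, keepdims=True)


_BETA_PARAMS = [(5.0, 45.0), (50.0, 50.0), (45.0, 5.0)]  # sharp components per type


def simulate_counts(design: SimDesign) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a count matrix, cell metadata, and ground truth from a design.

    Returns an :class:`anndata.AnnData` with raw integer counts in ``.X``
    (CSR), per-cell metadata in ``.obs`` (replicate, condition, class,
    subclass, type, doublet_score) and gene metadata in ``.var`` (name,
    is_mito), plus a :class:`GroundTruth` with per-cell artifact flags and
    per-gene program labels.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    prog = design.programs if design.programs is not None else build_programs(design)
    n_genes = design.n_genes
    baseline = prog["baseline"].to_numpy()
    theta = np.broadcast_to(np.asarray(design.dispersion, dtype=float), (n_genes,))
    sub_of_type = design.subclass_of_type()

    # per-(subclass) static marker effects and temporal effects
    log2_static = {s: np.zeros(n_genes) for s in design.subclasses}
    log2_temporal = {s: np.zeros(n_genes) for s in design.subclasses}
    for s in design.subclasses:
        m = (prog["program"] == "marker") & (prog["subclass"] == s)
        log2_static[s][m.to_numpy()] = prog.loc[m, "effect"]
        q1 = (prog["program"] == "q1") & (prog["subclass"] == s)
        log2_temporal[s][q1.to_numpy()] = prog.loc[q1, "effect"]
        q2 = prog["program"] == "q2"
        log2_temporal[s][q2.to_numpy()] += prog.loc[q2, "effect"]
    # per-type marker effects (static)
    log2_type = {}
    for t in design.all_types:
        m = (prog["program"] == "type_marker") & (prog["type"] == t)
        if m.any():
            v = np.zeros(n_genes)
            v[m.to_numpy()] = prog.loc[m, "effect"]
            log2_type[t] = v
    ieg = (prog["program"] == "ieg").to_numpy()
    ieg_effect = np.where(ieg, prog["effect"].to_numpy(), 0.0)

    blocks: list[sp.csr_matrix] = []
    obs_rows: list[pd.DataFrame] = []
    u_all: list[np.ndarray] = []
    himito_flags: list[np.ndarray] = []

    def draw_block(mu: np.ndarray) -> sp.csr_matrix:
        lam = rng.gamma(shape=theta[None, :], scale=mu / theta[None, :])
        return sp.csr_matrix(rng.poisson(lam).astype(np.int32))

    mu_sigma = design.library_size_lognormal
    for cond in design.conditions:
        tp = design.timepoint_of[cond]
        for s in design.subclasses:
            if s == design.continuum_subclass:
                n_cells = int(design.cells_per_type.loc[design.types_of[s], cond].sum())
                if n_cells == 0:
                    continue
                freqs = design.composition[cond].to_numpy(dtype=float)
                comp = rng.choice(len(freqs), size=n_cells, p=freqs)
                a = np.array([_BETA_PARAMS[c][0] for c in comp])
                b = np.array([_BETA_PARAMS[c][1] for c in comp])
                u = rng.beta(a, b)
                w = _continuum_memberships(u)
                types = np.array(design.types_of[s], dtype=object)[w.argmax(axis=1)]
                eff = np.stack([log2_type[t] for t in design.types_of[s]])
                log2_cells = w @ eff  # (cells, genes) type-marker effects
                base_log2 = log2_static[s] + (log2_temporal[s] if tp == "T2" else 0.0)
                log2_cells = log2_cells + base_log2[None, :]
            else:
                names = design.types_of[s]
                counts = design.cells_per_type.loc[names, cond].to_numpy(dtype=int)
                n_cells = int(counts.sum())
                if n_cells == 0:
                    continue
                types = np.repeat(np.array(names, dtype=object), counts)
                base_log2 = log2_static[s] + (log2_temporal[s] if tp == "T2" else 0.0)
                log2_cells = np.tile(base_log2, (n_cells, 1))
                for t in names:
                    if t in log2_type:
                        log2_cells[types == t] += log2_type[t][None, :]
                u = np.full(n_cells, np.nan)
            if cond.endswith("RWD"):
                log2_cells = log2_cells + ieg_effect[None, :]
            size = rng.lognormal(mu_sigma[0], mu_sigma[1], n_cells)
            mu = baseline[None, :] * np.exp2(log2_cells) * size[:, None]
            # high-mito (damaged) cells: partial identity loss toward the
            # baseline profile plus mitochondrial load boosted to 20-40%
            himito = rng.random(n_cells) < design.himito_rate
            if himito.any():
                mito_cols = prog["is_mito"].to_numpy()
                sub = 0.5 * mu[himito] + 0.5 * (baseline[None, :] * size[himito, None])
                f = rng.uniform(0.2, 0.4, int(himito.sum()))
                m_sum = sub[:, mito_cols].sum(axis=1)
                o_sum = sub[:, ~mito_cols].sum(axis=1)
                boost = f / (1 - f) * o_sum / np.maximum(m_sum, 1e-9)
                sub[:, mito_cols] *= boost[:, None]
                mu[himito] = sub
            himito_flags.append(himito)
            block = draw_block(np.maximum(mu, 1e-12))
            if himito.any():
                # mito load of damaged cells is a stable bulk fraction:
                # Poisson, not overdispersed, so the realized fraction
                # stays in the designed 20-40% band
                block = block.tolil()
                rows = np.flatnonzero(himito)
                cols = np.flatnonzero(mito_cols)
                block[np.ix_(rows, cols)] = rng.poisson(mu[np.ix_(rows, cols)])
                block = block.tocsr()
            blocks.append(block)
            obs_rows.append(pd.DataFrame({
                "condition": cond,
                "class": design.class_of[s],
                "subclass": s,
                "type": types,
            }))
            u_all.append(u)

    X = sp.vstack(blocks, format="csr")
    obs = pd.concat(obs_rows, ignore_index=True)
    obs["u"] = np.concatenate(u_all)
    n = X.shape[0]
    obs["is_doublet"] = False
    obs["is_lowq"] = False
    obs["is_himito"] = np.concatenate(himito_flags)
    mito_mask = prog["is_mito"].to_numpy()

    # low-quality cells: library thinned below the QC retention floor
    if design.lowq_rate > 0:
        cand = np.flatnonzero(~obs["is_himito"].to_numpy())
        k = int(round(design.lowq_rate * n))
        idx = rng.choice(cand, size=min(k, len(cand)), replace=False)
        X = X.tolil()
        for i in idx:
            target = rng.uniform(50, 400)
            row = np.asarray(X[i].todense()).ravel().astype(np.int64)
            total = row.sum()
            keep = rng.binomial(row, min(1.0, target / max(total, 1)))
            X[i] = keep
        X = X.tocsr()
        obs.loc[idx, "is_lowq"] = True

    # doublets: sums of two random singlet cells' draws
    if design.doublet_rate > 0:
        k = int(round(design.doublet_rate * n))
        i1 = rng.choice(n, size=k, replace=False)
        i2 = rng.choice(n, size=k, replace=False)
        D = X[i1] + X[i2]
        X = sp.vstack([X, D], format="csr")
        dobs = obs.iloc[i1].copy().reset_index(drop=True)
        dobs["is_doublet"] = True
        dobs["is_lowq"] = False
        dobs["is_himito"] = False
        obs = pd.concat([obs, dobs], ignore_index=True)

    n = X.shape[0]
    # synthetic external doublet score: imperfect but informative
    score = rng.beta(3, 6, n)
    dbl = obs["is_doublet"].to_numpy()
    score[dbl] = rng.beta(6, 3, int(dbl.sum()))
    obs["doublet_score"] = score
    # replicates assigned at random within condition
    rep = rng.integers(1, design.n_replicates + 1, n)
    obs["replicate"] = obs["condition"].to_numpy() + "_r" + rep.astype(str)

    barcodes = [f"cell{i:06d}" for i in range(n)]
    var = pd.DataFrame({
        "name": [f"gene{j:05d}" for j in range(n_genes)],
        "is_mito": mito_mask,
    }, index=[f"g{j:05d}" for j in range(n_genes)])
    var.index.name = "gene_id"

    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({
            "replicate": obs["replicate"].to_numpy(),
            "condition": obs["condition"].to_numpy(),
            "class": obs["class"].to_numpy(),
            "subclass": obs["subclass"].to_numpy(),
            "type": obs["type"].to_numpy(),
            "doublet_score": obs["doublet_score"].to_numpy(),
        }, index=barcodes),
        var=var,
    )
    adata.obs.index.name = "barcode"

    truth_cells = obs[["class", "subclass", "type", "is_doublet", "is_lowq",
                       "is_himito", "u"]].copy()
    truth_cells.index = pd.Index(barcodes, name="barcode")
    genes = prog.copy()
    genes.index = var.index.copy()

    if design.continuum_subclass is not None:
        tf = design.composition.copy()
    else:
        tf = pd.DataFrame(index=design.all_types, columns=design.conditions, dtype=float)
        for c in design.conditions:
            v = design.cells_per_type[c].to_numpy(dtype=float)
            tf[c] = v / v.sum() if v.sum() else 0.0
    truth = GroundTruth(cells=truth_cells, genes=genes, type_freqs=tf)
    return adata, truth


# ---------------------------------------------------------------------------
# fixture I/O (Matrix Market + TSV)


def write_fixture(adata: ad.AnnData, truth: GroundTruth | None, outdir: str | Path,
                  overwrite: bool = False) -> Path:
    """Write counts as MTX plus gene/cell/truth TSVs; round-trips losslessly."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X, field="integer")
    var = adata.var.reset_index()
    var.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    adata.obs.reset_index().to_csv(outdir / "cells.tsv", sep="\t", index=False)
    if truth is not None:
        truth.cells.reset_index().to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
        truth.genes.reset_index().to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        truth.type_freqs.rename_axis("type").reset_index().to_csv(
            outdir / "truth_type_freqs.tsv", sep="\t", index=False)
    return outdir


def read_fixture(indir: str | Path) -> tuple[ad.AnnData, GroundTruth | None]:
    """Read a fixture written by :func:`write_fixture`."""
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")), dtype=np.int32)
    var = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene_id")
    obs = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("barcode")
    for c in ("condition", "class", "subclass", "type", "replicate"):
        if c in obs:
            obs[c] = obs[c].astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth = None
    tc = indir / "truth_cells.tsv"
    if tc.exists():
        cells = pd.read_csv(tc, sep="\t").set_index("barcode")
        genes = pd.read_csv(indir / "truth_genes.tsv", sep="\t").set_index("gene_id")
        genes["truth_quadrant"] = genes["truth_quadrant"].fillna("")
        for c in ("subclass", "type"):
            genes[c] = genes[c].fillna("")
        tf = pd.read_csv(indir / "truth_type_freqs.tsv", sep="\t").set_index("type")
        truth = GroundTruth(cells=cells, genes=genes, type_freqs=tf)
    return adata, truth


def design_manifest(design: SimDesign) -> dict:
    """JSON-serializable snapshot of a design (for run manifests)."""
    d = dataclasses.asdict(design)
    d["cells_per_type"] = design.cells_per_type.to_dict()
    d["programs"] = None if design.programs is None else "built"
    d["composition"] = None if design.composition is None else design.composition.to_dict()
    d["dispersion"] = (float(design.dispersion) if np.isscalar(design.dispersion)
                       else list(np.asarray(design.dispersion, dtype=float)))
    json.dumps(d)  # ensure serializable
    return d
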