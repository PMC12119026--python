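import numpy as np
import pandas as pd
import pytest

from cortexdev import qc, simulate


def two_subclass_design(cells_per_group=200, n_genes=60, temporal_effect=2.0,
                        marker_effect=0.0, baseline=3.0, seed=0,
                        conditions=("T1", "T2"), dispersion=0.5):
    """Minimal design: two subclasses (one type each), two timepoints.

    Gene 0 carries a temporal effect in subclass A; gene 1 a static marker
    effect in subclass A; everything else is flat with the given baseline.
    """
    subclasses = ["A", "B"]
    types_of = {"A": ["A_1"], "B": ["B_1"]}
    cpt = pd.DataFrame(cells_per_group, index=["A_1", "B_1"],
                       columns=list(conditions), dtype=int)
    prog = pd.DataFrame({
        "program": ["background"] * n_genes,
        "subclass": [""] * n_genes,
        "type": [""] * n_genes,
        "effect": np.zeros(n_genes),
        "baseline": np.full(n_genes, float(baseline)),
        "is_mito": np.zeros(n_genes, dtype=bool),
    })
    if temporal_effect:
        prog.loc[0, ["program", "subclass", "effect"]] = ["q1", "A", temporal_effect]
    if marker_effect:
        prog.loc[1, ["program", "subclass", "effect"]] = ["marker", "A", marker_effect]
    quad = {"q1": "Q1", "marker": "Q4", "background": "Q3"}
    prog["truth_quadrant"] = prog["program"].map(quad)
    design = simulate.SimDesign(
        conditions=list(conditions),
        timepoint_of={c: ("T1" if i == 0 else "T2") for i, c in enumerate(conditions)},
        subclasses=subclasses,
        class_of={s: "glutamatergic" for s in subclasses},
        types_of=types_of,
        cells_per_type=cpt,
        n_genes=n_genes,
        n_mito_genes=0,
        programs=prog,
        dispersion=dispersion,
        seed=seed,
    )
    design.validate()
    return design


@pytest.fixture(scope="session")
def demo_dataset():
    """Full-featured small fixture: all programs, artifacts, 4 conditions."""
    design = simulate.default_design(cells_per_type=40, n_genes=1000, seed=11,
                                     doublet_rate=0.03, lowq_rate=0.03,
                                     himito_rate=0.03)
    adata, truth = simulate.simulate_counts(design)
    return design, adata, truth


@pytest.fixture(scope="session")
def continuum_dataset():
    """Continuum subclass only (3 types, compositional shift), two ages."""
    design = simulate.default_design(cells_per_type=0, n_genes=1000, seed=21,
                                     conditions=["P12", "P22"])
    for t in design.types_of["L23"]:
        design.cells_per_type.loc[t] = 400
    adata, truth = simulate.simulate_counts(design)
    qc.compute_qc_metrics(adata)
    adn = qc.normalize_log(qc.filter_cells(adata))
    return design, adn, truth
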