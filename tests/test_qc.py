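"""QC filters: exact strict inequalities, idempotence, order stability,
clustering determinism, mito-cluster removal, mapping-based purification."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from cortexdev import qc
from cortexdev.qc import ClusterAssignment


def toy_counts(count_rows):
    """Cells with the given total counts spread over 10 genes each."""
    n_genes = 20
    rows = []
    for total in count_rows:
        row = np.zeros(n_genes, dtype=int)
        per = total // 10
        row[:10] = per
        row[0] += total - per * 10
        rows.append(row)
    X = sp.csr_matrix(np.array(rows))
    a = ad.AnnData(X=X,
                   obs=pd.DataFrame(index=[f"c{i}" for i in range(len(count_rows))]),
                   var=pd.DataFrame({"is_mito": [False] * n_genes},
                                    index=[f"g{i}" for i in range(n_genes)]))
    return a


def test_filter_cells_strict_bounds_on_toy():
    a = toy_counts([400, 501, 39999, 40000, 600])
    kept = qc.filter_cells(a, max_genes=7000, max_counts=40000, min_counts=500)
    assert list(kept.obs_names) == ["c1", "c2", "c4"]  # strict <, > bounds


def test_filter_cells_boundary_n_genes():
    X = sp.csr_matrix(np.ones((2, 7000), dtype=int))
    X[1, 0] = 0  # second cell detects 6,999 genes
    a = ad.AnnData(X=X, obs=pd.DataFrame(index=["full", "one_less"]),
                   var=pd.DataFrame(index=[f"g{i}" for i in range(7000)]))
    kept = qc.filter_cells(a, max_genes=7000, max_counts=40000, min_counts=500)
    assert list(kept.obs_names) == ["one_less"]


def test_filter_cells_empty_result_warns():
    a = toy_counts([100, 200])
    with pytest.warns(UserWarning, match="all cells removed"):
        out = qc.filter_cells(a)
    assert out.n_obs == 0


def test_filter_cells_idempotent_and_order_stable():
    a = toy_counts([600, 501, 900, 400, 1200])
    once = qc.filter_cells(a)
    twice = qc.filter_cells(once)
    assert list(once.obs_names) == list(twice.obs_names) == ["c0", "c1", "c2", "c4"]


@pytest.mark.parametrize("n_detect,min_cells,kept", [(99, 100, False),
                                                     (100, 100, True),
                                                     (0, 1, False)])
def test_filter_genes_boundaries(n_detect, min_cells, kept):
    X = np.zeros((120, 2), dtype=int)
    X[:, 0] = 1                     # reference gene in all cells
    X[:n_detect, 1] = 1
    a = ad.AnnData(X=sp.csr_matrix(X),
                   obs=pd.DataFrame(index=[f"c{i}" for i in range(120)]),
                   var=pd.DataFrame(index=["ref", "probe"]))
    out = qc.filter_genes(a, min_cells=min_cells)
    assert ("probe" in out.var_names) == kept


def test_normalize_log_arithmetic():
    X = sp.csr_matrix(np.array([[2, 3, 5], [4, 4, 4]]))
    a = ad.AnnData(X=X, obs=pd.DataFrame(index=["c0", "c1"]),
                   var=pd.DataFrame(index=["g0", "g1", "g2"]))
    out = qc.normalize_log(a, target_sum=10000)
    dense = np.asarray(out.X.todense())
    np.testing.assert_allclose(dense[0], np.log1p([2000, 3000, 5000]), rtol=1e-9)
    assert len(set(np.round(dense[1], 12))) == 1  # all-equal cell stays uniform
    np.testing.assert_allclose(np.expm1(dense).sum(axis=1), 10000, rtol=1e-6)


def test_normalize_log_single_count_closed_form():
    X = sp.csr_matrix(np.array([[1, 4999]]))
    a = ad.AnnData(X=X, obs=pd.DataFrame(index=["c0"]),
                   var=pd.DataFrame(index=["g0", "g1"]))
    out = qc.normalize_log(a, target_sum=10000)
    assert np.isclose(out.X[0, 0], np.log(3.0))


def test_normalize_log_rejects_zero_count_cell():
    X = sp.csr_matrix(np.array([[0, 0], [1, 1]]))
    a = ad.AnnData(X=X, obs=pd.DataFrame(index=["c0", "c1"]),
                   var=pd.DataFrame(index=["g0", "g1"]))
    with pytest.raises(ValueError, match="zero-count"):
        qc.normalize_log(a)


def _blob_adata(seed=0, n_per=150, n_genes=60, shift=12.0):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(1.0, 0.3, n_genes)
    mu1 = base.copy()
    mu2 = base.copy()
    mu2[: n_genes // 2] *= shift
    X = np.vstack([rng.poisson(mu1, (n_per, n_genes)),
                   rng.poisson(mu2, (n_per, n_genes))])
    a = ad.AnnData(X=sp.csr_matrix(X),
                   obs=pd.DataFrame({"truth": [0] * n_per + [1] * n_per},
                                    index=[f"c{i}" for i in range(2 * n_per)]),
                   var=pd.DataFrame(index=[f"g{i}" for i in range(n_genes)]))
    return qc.normalize_log(a)


def test_cluster_pipeline_recovers_planted_blobs_and_is_deterministic():
    a = _blob_adata()
    c1 = qc.cluster_pipeline(a, n_hvg=40, n_pcs=10, resolution=0.3, seed=0)
    assert adjusted_rand_score(a.obs["truth"], c1.labels) == 1.0
    c2 = qc.cluster_pipeline(a, n_hvg=40, n_pcs=10, resolution=0.3, seed=0)
    assert np.array_equal(c1.labels, c2.labels)
    assert c1.labels.min() == 0
    assert set(np.unique(c1.labels)) == set(range(len(np.unique(c1.labels))))


def test_cluster_pipeline_single_blob_low_resolution():
    a = _blob_adata(shift=1.0)
    c = qc.cluster_pipeline(a, n_hvg=40, n_pcs=10, resolution=0.1, seed=0)
    assert len(np.unique(c.labels)) == 1


def test_cluster_pipeline_requires_enough_cells():
    a = _blob_adata(n_per=5)
    with pytest.raises(ValueError, match="k_neighbors"):
        qc.cluster_pipeline(a, k_neighbors=50)


def _mito_clustered_adata():
    a = toy_counts([1000] * 9)
    a.var["is_mito"] = [True] + [False] * 19
    qc.compute_qc_metrics(a)
    # override with designed mito fractions
    a.obs["percent_mito"] = [0.30, 0.28, 0.32, 0.07, 0.06, 0.08, 0.05, 0.05, 0.05]
    labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
    summaries = pd.DataFrame({
        "size": [3, 3, 3],
        "mean_percent_mito": [0.30, 0.07, 0.05],
    }, index=[0, 1, 2])
    return a, ClusterAssignment(labels=labels, resolution=1.0, summaries=summaries)


def test_remove_mito_clusters_threshold_behavior():
    a, cl = _mito_clustered_adata()
    out, labels = qc.remove_mito_clusters(a, cl, mito_threshold=0.2)
    assert out.n_obs == 6 and set(labels) == {1, 2}   # 0.30 cluster removed
    out2, _ = qc.remove_mito_clusters(a, cl, mito_threshold=1.0)
    assert out2.n_obs == 9                            # nothing removed


def test_purify_by_mapping_minor_components_and_diffuse_rule():
    n = 1000
    a = toy_counts([1000] * (n + 10))
    clusters = np.array([0] * n + [1] * 10)
    assigned = np.array(["X"] * 15 + ["Y"] * (n - 15) + ["Z"] * 10, dtype=object)
    mapping = pd.DataFrame({"assigned": assigned,
                            "max_prob": [0.9] * n + [0.9] * 10},
                           index=a.obs_names)
    out, removed = qc.purify_by_mapping(a, clusters, mapping, min_component=0.02)
    assert removed["minor_component_cells"] == 15     # 1.5% < 2% component
    assert out.n_obs == n + 10 - 15
    # a cluster mapping 100% to one label is untouched
    assert (pd.Series(out.obs_names).str.len() > 0).all()
    # diffuse cluster: max share 0.30 and mean prob 0.4 -> removed whole
    assigned2 = np.array((["P"] * 30 + ["Q"] * 35 + ["R"] * 35) * 10, dtype=object)[:n]
    mapping2 = pd.DataFrame({"assigned": np.concatenate([assigned2, ["Z"] * 10]),
                             "max_prob": [0.4] * n + [0.9] * 10},
                            index=a.obs_names)
    out2, removed2 = qc.purify_by_mapping(a, clusters, mapping2)
    assert removed2["diffuse_clusters"] == [0]
    assert out2.n_obs == 10


def test_purify_by_mapping_requires_full_coverage():
    a = toy_counts([1000] * 4)
    mapping = pd.DataFrame({"assigned": ["X"], "max_prob": [1.0]},
                           index=[a.obs_names[0]])
    with pytest.raises(ValueError, match="cover"):
        qc.purify_by_mapping(a, np.zeros(4, dtype=int), mapping)


def test_planted_artifacts_removed_with_high_recall(demo_dataset):
    """Planted low-quality and high-mito populations are removed at default
    thresholds with recall >= 0.95."""
    _, adata, truth = demo_dataset
    adata = adata.copy()
    qc.compute_qc_metrics(adata)
    kept1 = qc.filter_cells(adata)
    lowq = truth.cells["is_lowq"]
    removed = set(adata.obs_names) - set(kept1.obs_names)
    assert len(removed & set(lowq.index[lowq])) / lowq.sum() >= 0.95
    kept1 = qc.filter_genes(kept1, min_cells=20)
    adn = qc.normalize_log(kept1)
    cl = qc.cluster_pipeline(adn, n_hvg=500, n_pcs=40, resolution=1.5, seed=0)
    purged, _ = qc.remove_mito_clusters(adn, cl, 0.2)
    him = truth.cells.loc[adn.obs_names, "is_himito"]
    removed2 = set(adn.obs_names) - set(purged.obs_names)
    assert len(removed2 & set(him.index[him])) / him.sum() >= 0.95
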