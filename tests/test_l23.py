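"""Continuum analysis: marker selection, PCA determinism and spectra,
eigenvector correspondence, marker scores, KS comparisons, PC1 profiles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cortexdev.l23 import (eigenvector_correspondence, ks_compare, marker_score,
                           pca_condition, pc1_profile, select_type_markers)


class TestMarkerSelection:
    def test_planted_marker_blocks_recovered(self, continuum_dataset):
        design, adn, truth = continuum_dataset
        sel = (adn.obs["subclass"] == "L23").to_numpy()
        ref = sel & (adn.obs["condition"] == "P22").to_numpy()
        genes = np.array(adn.var_names)
        m = select_type_markers(adn.X[ref], adn.obs["type"].to_numpy()[ref], genes)
        tg = truth.genes
        for t in design.types_of["L23"]:
            planted = set(tg.index[(tg["program"] == "type_marker") & (tg["type"] == t)])
            recovered = len(planted & set(m[t])) / len(planted)
            assert recovered >= 0.9, (t, recovered)

    def test_type_identical_to_rest_gets_no_markers(self):
        rng = np.random.default_rng(0)
        x = np.log1p(rng.poisson(5.0, size=(300, 30)).astype(float))
        x[:100, :5] = np.log1p(rng.poisson(40.0, size=(100, 5)))
        labels = np.repeat(["hot", "flat1", "flat2"], 100)
        m = select_type_markers(x, labels, [f"g{i}" for i in range(30)])
        assert len(m["hot"]) >= 4
        assert m["flat1"] == [] and m["flat2"] == []

    def test_fold_change_gate_is_strict(self):
        # a tie-only gene at exactly 1.5x mean ratio cannot pass (p = 1 and
        # the strict > gate both exclude it); a strong gene does pass
        x = np.zeros((200, 2))
        x[:100, 0] = np.log1p(3.0)
        x[100:, 0] = np.log1p(2.0)
        rng = np.random.default_rng(1)
        x[:100, 1] = np.log1p(rng.poisson(20.0, 100))
        x[100:, 1] = np.log1p(rng.poisson(2.0, 100))
        m = select_type_markers(x, np.repeat(["a", "b"], 100), ["ratio15", "strong"])
        assert "ratio15" not in m["a"]
        assert "strong" in m["a"]

    def test_requires_two_types(self):
        with pytest.raises(ValueError, match="two types"):
            select_type_markers(np.ones((10, 3)), ["a"] * 10, list("xyz"))


class TestPCA:
    def test_rank_two_data_shows_spectral_gap(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(500, 2))
        v = rng.normal(size=(2, 40))
        x = u @ v + rng.normal(scale=0.05, size=(500, 40))
        genes = [f"g{i}" for i in range(40)]
        e = pca_condition(x, genes, genes, n_components=6)
        assert e.variance_fraction[1] > 20 * e.variance_fraction[2]

    def test_duplicated_dataset_same_spectrum_and_determinism(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 20))
        genes = [f"g{i}" for i in range(20)]
        e1 = pca_condition(x, genes, genes, n_components=5)
        e2 = pca_condition(np.vstack([x, x]), genes, genes, n_components=5)
        np.testing.assert_allclose(e1.variance_fraction, e2.variance_fraction,
                                   atol=1e-9)
        e3 = pca_condition(x, genes, genes, n_components=5)
        np.testing.assert_allclose(e1.loadings, e3.loadings)

    def test_loadings_orthonormal_and_variance_sums_to_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 10))
        genes = [f"g{i}" for i in range(10)]
        e = pca_condition(x, genes, genes, n_components=10)
        np.testing.assert_allclose(e.loadings @ e.loadings.T, np.eye(10), atol=1e-8)
        assert e.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(e.variance_fraction) <= 1e-12).all()

    def test_fewer_cells_than_components_rejected(self):
        with pytest.raises(ValueError, match="fewer cells"):
            pca_condition(np.ones((3, 10)), [f"g{i}" for i in range(10)],
                          [f"g{i}" for i in range(10)], n_components=5)


class TestCorrespondence:
    def test_self_correspondence_is_identity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 15))
        genes = [f"g{i}" for i in range(15)]
        e = pca_condition(x, genes, genes, n_components=3)
        M, oto = eigenvector_correspondence(e, e, n=3)
        np.testing.assert_allclose(M, np.eye(3), atol=1e-9)
        assert oto

    def test_sign_flips_do_not_matter(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(80, 15))
        genes = [f"g{i}" for i in range(15)]
        e1 = pca_condition(x, genes, genes, n_components=2)
        e2 = pca_condition(x, genes, genes, n_components=2)
        e2.loadings = -e2.loadings
        M, oto = eigenvector_correspondence(e1, e2, n=2)
        np.testing.assert_allclose(M, np.eye(2), atol=1e-9)
        assert oto

    def test_mismatched_features_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 6))
        g1 = [f"g{i}" for i in range(6)]
        g2 = list(reversed(g1))
        e1 = pca_condition(x, g1, g1, n_components=2)
        e2 = pca_condition(x, g2, g2, n_components=2)
        with pytest.raises(ValueError, match="feature"):
            eigenvector_correspondence(e1, e2)


class TestMarkerScore:
    def test_singleton_and_pair_arithmetic(self):
        x = np.array([[2.0, 4.0, 9.0]])
        genes = ["a", "b", "c"]
        assert marker_score(x, genes, ["c"])[0] == 9.0
        assert marker_score(x, genes, ["a", "b"])[0] == 3.0
        with pytest.raises(ValueError, match="empty"):
            marker_score(x, genes, [])

    def test_type_score_separates_planted_types(self, continuum_dataset):
        design, adn, truth = continuum_dataset
        sel = (adn.obs["subclass"] == "L23").to_numpy()
        genes = np.array(adn.var_names)
        tg = truth.genes
        ty = adn.obs["type"].to_numpy()[sel]
        markers_a = tg.index[(tg["program"] == "type_marker") & (tg["type"] == "L23_A")]
        score = marker_score(adn.X[sel], genes, list(markers_a))
        auc = roc_auc_score(ty == "L23_A", score)
        assert auc >= 0.9

    def test_continuum_types_occupy_triangle_extremes(self, continuum_dataset):
        design, adn, truth = continuum_dataset
        sel = (adn.obs["subclass"] == "L23").to_numpy()
        genes = np.array(adn.var_names)
        tg = truth.genes
        union = list(tg.index[tg["program"] == "type_marker"])
        e = pca_condition(adn.X[sel], genes, union, n_components=2)
        ty = adn.obs["type"].to_numpy()[sel]
        cents, spreads = {}, {}
        for t in design.types_of["L23"]:
            pts = e.scores[ty == t, :2]
            cents[t] = pts.mean(axis=0)
            spreads[t] = pts.std(axis=0).mean()
        names = design.types_of["L23"]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                dist = np.linalg.norm(cents[a] - cents[b])
                assert dist > 2 * max(spreads[a], spreads[b])


class TestKS:
    def test_identical_samples(self):
        d, p = ks_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0 and p == 1.0

    def test_disjoint_samples_have_d_one(self):
        d, _ = ks_compare([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="two observations"):
            ks_compare([1.0], [1.0, 2.0])

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 60
        for _ in range(reps):
            a, b = rng.normal(size=(2, 300))
            _, p = ks_compare(a, b)
            rejections += p < 0.05
        assert rejections / reps < 0.12


class TestPc1Profile:
    def test_identical_conditions_overlap(self):
        rng = np.random.default_rng(1)
        score = rng.normal(size=200)
        pc1 = rng.normal(size=200)
        scores = {"A": np.concatenate([score, score])}
        cond = np.array(["x"] * 200 + ["y"] * 200)
        curves, ks = pc1_profile(scores, np.concatenate([pc1, pc1]), cond)
        assert ks["D"].iloc[0] == 0.0 and ks["p"].iloc[0] == 1.0

    def test_full_window_gives_constant_global_mean(self):
        rng = np.random.default_rng(2)
        score = rng.normal(size=100)
        cond = np.array(["x"] * 100)
        curves, _ = pc1_profile({"A": score}, np.arange(100.0), cond,
                                window_frac=1.0)
        np.testing.assert_allclose(curves["score"], score.mean(), atol=1e-12)

    def test_planted_shift_detected_along_pc1(self, continuum_dataset):
        design, adn, truth = continuum_dataset
        sel = (adn.obs["subclass"] == "L23").to_numpy()
        genes = np.array(adn.var_names)
        cond = adn.obs["condition"].to_numpy()[sel]
        tg = truth.genes
        union = list(tg.index[tg["program"] == "type_marker"])
        e = pca_condition(adn.X[sel], genes, union, n_components=2)
        scores = {t: marker_score(adn.X[sel], genes,
                                  list(tg.index[(tg["program"] == "type_marker")
                                                & (tg["type"] == t)]))
                  for t in design.types_of["L23"]}
        _, ks = pc1_profile(scores, e.scores[:, 0], cond)
        assert ks.loc[ks["type"] == "L23_A", "p"].min() < 0.01
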