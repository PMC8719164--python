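"""QC metrics, strict filter bounds, normalization and scaling conventions."""

import mscheter as m
import numpy as np
import pandas as pd
import pytest
from conftest import make_adata
from sklearn.metrics import roc_auc_score


class TestMetrics:
    def test_direct_arithmetic(self):
        ad_ = make_adata([[5, 45]], genes=["MT-A", "GENE-B"])
        met = m.compute_qc_metrics(ad_)
        assert met["mito_fraction"].iloc[0] == pytest.approx(0.10)
        assert met["total_umi"].iloc[0] == 50
        assert met["n_expressed_genes"].iloc[0] == 2

    def test_no_mito_expression(self):
        ad_ = make_adata([[0, 7, 3]], genes=["MT-A", "B", "C"])
        assert m.compute_qc_metrics(ad_)["mito_fraction"].iloc[0] == 0.0

    def test_all_zero_cell(self):
        ad_ = make_adata([[0, 0], [1, 2]], genes=["MT-A", "B"])
        met = m.compute_qc_metrics(ad_)
        assert met["total_umi"].iloc[0] == 0
        assert met["n_expressed_genes"].iloc[0] == 0
        assert met["mito_fraction"].iloc[0] == 0.0

    def test_empty_prefix_rejected(self):
        with pytest.raises(ValueError):
            m.compute_qc_metrics(make_adata([[1]]), mito_prefix="")


class TestFilter:
    def _metrics(self, genes, mito, score):
        n = len(genes)
        return pd.DataFrame({
            "n_expressed_genes": genes,
            "total_umi": [1000] * n,
            "mito_fraction": mito,
            "doublet_score": score,
        }, index=[f"c{i}" for i in range(n)])

    def test_boundaries_are_strict(self):
        """Cells at exactly 4000 genes or 10% mito are retained."""
        met = self._metrics([4000, 4001, 500, 499, 1000, 1000],
                            [0.0, 0.0, 0.0, 0.0, 0.10, 0.100001],
                            [0.0] * 6)
        ad_ = make_adata(np.ones((6, 2)))
        kept, rep = m.filter_cells(ad_, met)
        assert list(kept.obs_names) == ["c0", "c2", "c4"]
        assert rep.high_genes == 1 and rep.low_genes == 1 and rep.high_mito == 1

    def test_planted_violations_enumerated(self):
        """5-cell toy, one violation per rule: exactly those cells are removed."""
        met = self._metrics([100, 4500, 1000, 1000, 1000],
                            [0.0, 0.0, 0.5, 0.0, 0.0],
                            [0.0, 0.0, 0.0, 0.9, 0.0])
        ad_ = make_adata(np.ones((5, 2)))
        kept, rep = m.filter_cells(ad_, met)
        assert list(kept.obs_names) == ["c4"]
        assert (rep.low_genes, rep.high_genes, rep.high_mito,
                rep.high_doublet_score) == (1, 1, 1, 1)

    def test_all_removed_is_error(self):
        met = self._metrics([10], [0.0], [0.0])
        with pytest.raises(ValueError):
            m.filter_cells(make_adata(np.ones((1, 2))), met)

    def test_idempotent(self, small_dataset):
        met = m.compute_qc_metrics(small_dataset)
        met["doublet_score"] = 0.0
        kept, _ = m.filter_cells(small_dataset, met, min_genes=50, max_genes=10000)
        met2 = m.compute_qc_metrics(kept)
        met2["doublet_score"] = 0.0
        kept2, rep2 = m.filter_cells(kept, met2, min_genes=50, max_genes=10000)
        assert rep2.n_kept == rep2.n_input

    def test_exact_recovery_of_planted_violations(self):
        cfg = m.SimulationConfig(n_cells=600, n_genes=4500, doublet_rate=0.0, seed=21)
        d = m.simulate_counts(cfg)
        planted = m.plant_qc_violations(d, n_low_genes=8, n_high_genes=6,
                                        n_high_mito=5, n_high_doublet=4, seed=22)
        met = m.compute_qc_metrics(d)
        met["doublet_score"] = 0.0
        met.iloc[planted["high_doublet_score"],
                 met.columns.get_loc("doublet_score")] = planted["planted_doublet_score"]
        _, rep = m.filter_cells(d, met)
        assert (rep.low_genes, rep.high_genes, rep.high_mito,
                rep.high_doublet_score) == (8, 6, 5, 4)


class TestDoubletScore:
    def test_separates_planted_doublets(self, two_cluster_doublets):
        d = two_cluster_doublets
        scores = m.score_doublets(d, expected_rate=0.08, seed=13)
        auroc = roc_auc_score(d.obs["is_doublet"].to_numpy(), scores)
        assert auroc > 0.9

    def test_deterministic(self, two_cluster_doublets):
        s1 = m.score_doublets(two_cluster_doublets, seed=5)
        s2 = m.score_doublets(two_cluster_doublets, seed=5)
        np.testing.assert_array_equal(s1, s2)

    def test_duplicate_cells_symmetric(self):
        """Duplicated cells are interchangeable: equal scores up to ties."""
        rng = np.random.default_rng(0)
        base = rng.poisson(5.0, size=(30, 50))
        ad_ = make_adata(np.vstack([base, base]))
        s = m.score_doublets(ad_, k_neighbors=5, seed=1)
        assert s.shape == (60,)
        assert (s >= 0).all() and (s <= 1).all()

    def test_too_many_neighbors_rejected(self):
        ad_ = make_adata(np.ones((10, 5)))
        with pytest.raises(ValueError):
            m.score_doublets(ad_, k_neighbors=10)

    def test_minimum_one_simulated_doublet(self, caplog):
        ad_ = make_adata(np.random.default_rng(1).poisson(5, (40, 30)))
        s = m.score_doublets(ad_, n_simulated_multiplier=0.0, k_neighbors=3, seed=2)
        assert np.isfinite(s).all()


class TestNormalize:
    def test_direct_arithmetic(self):
        counts = np.zeros((3, 3))
        counts[0] = [10, 40, 50]    # total 100
        counts[1] = [200, 0, 0]     # total 200
        counts[2] = [100, 100, 100]  # total 300
        norm = m.normalize(make_adata(counts))
        # median total = 200; cell 0 gene 0: 10/100*200 = 20
        assert norm.X[0, 0] == pytest.approx(20.0)
        assert norm.uns["median_total"] == 200.0

    def test_equal_totals_identity(self):
        counts = np.array([[1, 2, 3], [3, 2, 1], [2, 2, 2]], dtype=float)
        norm = m.normalize(make_adata(counts))
        np.testing.assert_allclose(norm.X.toarray(), counts)

    def test_single_cell_identity(self):
        counts = np.array([[4, 6]], dtype=float)
        norm = m.normalize(make_adata(counts))
        np.testing.assert_allclose(norm.X.toarray(), counts)

    def test_preserves_proportions(self, small_dataset):
        norm = m.normalize(small_dataset)
        X = small_dataset.X.toarray().astype(float)
        Xn = norm.X.toarray()
        p_raw = X / X.sum(axis=1, keepdims=True)
        p_norm = Xn / Xn.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(p_norm, p_raw, atol=1e-12)

    def test_zero_total_cell_stays_zero(self):
        counts = np.array([[0, 0], [5, 5]], dtype=float)
        norm = m.normalize(make_adata(counts))
        assert norm.X[0].sum() == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            m.normalize(make_adata(np.zeros((2, 2))))


class TestScale:
    def test_closed_form_unbiased_sd(self):
        """[1,2,3] with ddof=1 has sd 1, so scales to [-1, 0, 1]."""
        ad_ = make_adata(np.ones((3, 1)))
        ad_.X = np.array([[1.0], [2.0], [3.0]])
        Z = m.scale_genes(ad_, log_transform=False)
        np.testing.assert_allclose(Z.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_gene_zeroed(self):
        counts = np.array([[5, 1], [5, 2], [5, 9]], dtype=float)
        ad_ = make_adata(counts)
        ad_.X = counts  # bypass normalization, scale directly
        Z = m.scale_genes(ad_, log_transform=False)
        assert (Z[:, 0] == 0).all()

    def test_moments(self, small_norm):
        Z = m.scale_genes(small_norm)
        nonconst = Z.std(axis=0) > 0
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z[:, nonconst].var(axis=0, ddof=1) - 1).max() < 1e-6

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        ad_ = make_adata(np.ones((50, 4)))
        ad_.X = X
        Z = m.scale_genes(ad_, log_transform=False)
        np.testing.assert_allclose(Z, X, atol=1e-9)

    def test_needs_two_cells(self):
        with pytest.raises(ValueError):
            m.scale_genes(make_adata(np.ones((1, 3))))
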