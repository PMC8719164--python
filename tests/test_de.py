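"""Wilcoxon DE with Bonferroni, one-vs-rest markers, hypergeometric ORA."""

import itertools
import math

import mscheter as m
import numpy as np
import pandas as pd
import pytest
from scipy import stats


def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided p over all C(n, na) rank assignments."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    obs = ranks[:na].sum()
    mean = na * (n + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), na):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    @pytest.mark.parametrize("a,b", [
        ([1, 2, 3], [4, 5, 6]),
        ([1, 5, 9], [2, 3, 11, 12]),
        ([10, 2], [3, 4, 5, 6]),
        ([1, 7, 3, 9], [2, 8, 4, 10]),
    ])
    def test_matches_exact_enumeration(self, a, b):
        _, p = m.wilcoxon_rank_sum(np.array(a, float), np.array(b, float))
        assert p == pytest.approx(exact_rank_sum_p(np.array(a), np.array(b)),
                                  abs=1e-12)

    def test_all_extreme_case(self):
        """[1,2,3] vs [4,5,6]: 2 of C(6,3)=20 assignments are as extreme."""
        _, p = m.wilcoxon_rank_sum(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_constant_data_p_one(self):
        _, p = m.wilcoxon_rank_sum(np.array([2.0, 2, 2]), np.array([2.0, 2]))
        assert p == 1.0


class TestDifferentialExpression:
    def _toy(self, seed=0, n=60, g=20):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(size=(n, g))
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        return X, labels

    def test_swap_symmetry(self):
        X, labels = self._toy()
        ab = m.differential_expression(X, labels, "a", "b")
        ba = m.differential_expression(X, labels, "b", "a")
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-15)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        half = rng.lognormal(size=(30, 10))
        X = np.vstack([half, half])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        df = m.differential_expression(X, labels, "a", "b")
        np.testing.assert_allclose(df["log2fc"], 0.0, atol=1e-12)
        assert not df["significant"].any()

    def test_bonferroni_monotone_in_gene_count(self):
        X, labels = self._toy(seed=2)
        p_few = m.differential_expression(X[:, :5], labels, "a", "b")["adj_p"]
        p_many = m.differential_expression(X, labels, "a", "b")["adj_p"]
        assert (p_many.to_numpy()[:5] >= p_few.to_numpy() - 1e-15).all()
        df = m.differential_expression(X, labels, "a", "b")
        assert (df["adj_p"] >= df["p"] - 1e-15).all()

    def test_small_group_rejected(self):
        X, _ = self._toy()
        labels = np.array(["a"] + ["b"] * 59)
        with pytest.raises(ValueError):
            m.differential_expression(X, labels, "a", "b")

    def test_planted_markers_recovered(self, small_dataset, small_norm):
        X = small_norm.X.toarray()
        labels = small_dataset.obs["subpop"].to_numpy()
        genes = list(small_dataset.var_names)
        df = m.cluster_specific_genes(X, labels, "subpop0", genes=genes)
        program = small_dataset.uns["programs"]["subpop0"]
        assert df.loc[program, "specific"].all()


class TestClusterSpecific:
    def test_single_cluster_rejected(self):
        X = np.random.default_rng(0).lognormal(size=(10, 4))
        with pytest.raises(ValueError):
            m.cluster_specific_genes(X, np.array(["a"] * 10), "a")

    def test_shared_marker_specific_to_both(self):
        """A gene up in A and B equally vs C is specific in both lists."""
        rng = np.random.default_rng(3)
        n = 40
        X = rng.lognormal(sigma=0.1, size=(3 * n, 3))
        X[: 2 * n, 0] *= 8.0  # gene 0 high in A and B, low in C
        labels = np.array(["A"] * n + ["B"] * n + ["C"] * n)
        for grp in ("A", "B"):
            df = m.cluster_specific_genes(X, labels, grp, genes=["g0", "g1", "g2"])
            assert df.loc["g0", "specific"]


class TestOverrepresentation:
    def test_hand_summed_hypergeometric(self):
        """Universe 20, term 5, list 5, overlap 4: p = (C(5,4)C(15,1)+C(5,5))/C(20,5)."""
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        gene_list = universe[:4] + [universe[10]]
        df = m.overrepresentation(gene_list, {"t": term}, universe)
        expected = (math.comb(5, 4) * math.comb(15, 1) + math.comb(5, 5)) / math.comb(20, 5)
        assert df.loc["t", "p"] == pytest.approx(expected, rel=1e-12)

    def test_perfect_enrichment_is_minimum_p(self):
        universe = [f"g{i}" for i in range(50)]
        ann = {"hit": universe[:5], "other": universe[20:30], "third": universe[30:45]}
        df = m.overrepresentation(universe[:5], ann, universe)
        assert df["p"].idxmin() == "hit"

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            m.overrepresentation(["x"], {"t": ["a"]}, ["a", "b"])

    def test_null_p_uniform(self):
        """Random draws give roughly uniform p (KS test at alpha 0.01)."""
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(200)]
        term = universe[:40]
        pvals = []
        for _ in range(100):
            draw = list(rng.choice(universe, size=20, replace=False))
            pvals.append(m.overrepresentation(draw, {"t": term}, universe).loc["t", "p"])
        # discrete p-values are conservative; KS should still not reject badly
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01 or np.mean(pvals) > 0.3
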