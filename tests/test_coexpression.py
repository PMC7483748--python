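"""Soft-power adjacency, topological overlap and module detection."""

import numpy as np
import pytest

from geneprio import coexpression as cx
from geneprio.synthetic import simulate_block_expression
from .conftest import make_expression


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop unsigned TOM oracle."""
    n = a.shape[0]
    tom = np.eye(n)
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(n, rng):
    c = rng.uniform(-1, 1, size=(n, n))
    c = (c + c.T) / 2
    a = np.abs(c) ** 6
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.arange(5, dtype=float)
        em = make_expression(np.vstack([2**x - 1, 2 ** (2 * x + 1) - 1]), ["t"] * 5)
        adj = cx.adjacency(em, beta=7)
        assert adj.a[0, 1] == pytest.approx(1.0)

    def test_half_correlation_beta6(self):
        # two profiles engineered to |cor| = 0.5 on the log2 scale
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(5, 1, size=(3, 50))
            em = make_expression(np.clip(2**X - 1, 0, None), ["t"] * 50)
            adj = cx.adjacency(em, beta=6)
            cor = np.corrcoef(np.log2(em.values + 1))
            assert adj.a[0, 1] == pytest.approx(abs(cor[0, 1]) ** 6, abs=1e-9)

    def test_beta_one_equals_abs_correlation(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 50, size=(6, 10))
        em = make_expression(X, ["t"] * 10)
        adj = cx.adjacency(em, beta=1)
        cor = np.corrcoef(np.log2(X + 1))
        assert np.allclose(adj.a, np.abs(cor))

    def test_raising_beta_decreases_entries(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 50, size=(5, 12))
        em = make_expression(X, ["t"] * 12)
        a1 = cx.adjacency(em, beta=2).a
        a2 = cx.adjacency(em, beta=6).a
        off = ~np.eye(5, dtype=bool)
        assert (a2[off] <= a1[off] + 1e-12).all()

    def test_beta_below_one_rejected(self):
        em = make_expression(np.random.default_rng(0).uniform(0, 9, (3, 5)), ["t"] * 5)
        with pytest.raises(ValueError, match="beta"):
            cx.adjacency(em, beta=0)

    def test_hand_pearson_power_on_4_gene_fixture(self):
        X = np.array([[1.0, 2, 3, 4], [2, 4, 6, 8.1], [9, 1, 5, 5], [0, 0, 3, 1]])
        em = make_expression(np.clip(2**X - 1, 0, None), ["t"] * 4)
        adj = cx.adjacency(em, beta=6)
        for i in range(4):
            for j in range(4):
                xi, xj = X[i], X[j]
                num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
                den = np.sqrt(np.sum((xi - xi.mean()) ** 2)
                              * np.sum((xj - xj.mean()) ** 2))
                assert adj.a[i, j] == pytest.approx(abs(num / den) ** 6, abs=1e-10)


class TestTOM:
    def test_two_gene_tom_equals_adjacency(self):
        a = np.array([[1.0, 0.37], [0.37, 1.0]])
        tom = cx.topological_overlap(cx.AdjacencyMatrix(["g1", "g2"], a, 6))
        assert tom[0, 1] == pytest.approx(0.37)

    def test_identity_adjacency_gives_identity_tom(self):
        tom = cx.topological_overlap(cx.AdjacencyMatrix(list("abc"), np.eye(3), 6))
        assert np.allclose(tom, np.eye(3))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = random_adjacency(6, rng)
            tom = cx.topological_overlap(cx.AdjacencyMatrix(list("abcdef"), a, 6))
            assert np.allclose(tom, brute_force_tom(a), atol=1e-10)

    def test_tom_bounded_and_symmetric(self):
        rng = np.random.default_rng(5)
        for n in (4, 7, 12):
            a = random_adjacency(n, rng)
            tom = cx.topological_overlap(cx.AdjacencyMatrix([str(i) for i in range(n)], a, 6))
            assert np.allclose(tom, tom.T)
            assert tom.min() >= -1e-12 and tom.max() <= 1 + 1e-12


class TestFilterGenes:
    def test_constant_gene_removed_variable_kept(self):
        X = np.array([[5.0, 5, 5, 5], [1, 2, 3, 4], [0, 0, 0, 0]])
        em = make_expression(X, ["t"] * 4)
        out = cx.filter_genes(em)
        assert out.gene_ids == ["g2"]

    def test_mixed_fixture_matches_variance_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 9, size=(20, 6))
        X[rng.choice(20, 5, replace=False)] = 3.0  # constant rows
        em = make_expression(X, ["t"] * 6)
        kept = cx.filter_genes(em).gene_ids
        expected = [f"g{i + 1}" for i in range(20) if np.var(X[i]) > 0]
        assert kept == expected


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        em, labels = simulate_block_expression(n_per_block=40, n_blocks=2, seed=0)
        tom = cx.topological_overlap(cx.adjacency(em, beta=6))
        mods = cx.detect_modules(tom, em, min_size=30)
        pred = np.array([mods.module_of(g) for g in em.gene_ids])
        assert mods.n_modules == 2
        # label-agreement: same-block pairs together, cross-block apart
        for b in (1, 2):
            block = pred[labels == b]
            assert len(set(block)) == 1
        assert set(pred[labels == 1]) != set(pred[labels == 2])

    def test_min_size_sends_small_clusters_to_unassigned(self):
        em, _ = simulate_block_expression(n_per_block=10, n_blocks=2, seed=1)
        tom = cx.topological_overlap(cx.adjacency(em, beta=6))
        mods = cx.detect_modules(tom, em, min_size=30)
        assert mods.n_modules == 0
        assert all(v == 0 for v in mods.labels.values())

    def test_identical_blocks_merged(self):
        # two blocks driven by the SAME latent factor -> eigengene cor ~ 1
        rng = np.random.default_rng(0)
        factor = rng.normal(0, 1, 30)
        X = (np.tile(rng.uniform(1, 6, 80)[:, None], (1, 30))
             + factor[None, :] + rng.normal(0, 0.3, (80, 30)))
        em = make_expression(np.clip(2.0**X - 1, 0, None), ["t"] * 30)
        tom = cx.topological_overlap(cx.adjacency(em, beta=6))
        mods = cx.detect_modules(tom, em, min_size=30, merge_threshold=0.2)
        assert mods.n_modules == 1


class TestModuleTissueCorrelation:
    def _modules_from(self, em):
        tom = cx.topological_overlap(cx.adjacency(em, beta=6))
        return cx.detect_modules(tom, em, min_size=10)

    def test_tissue_specific_module_correlates(self):
        rng = np.random.default_rng(0)
        tissues = ["T"] * 10 + ["U"] * 10
        X = np.tile(rng.uniform(1, 4, 40)[:, None], (1, 20))
        X[:20, :10] += 4.0  # first 20 genes expressed only in tissue T
        X += rng.normal(0, 0.3, X.shape)
        em = make_expression(np.clip(2.0**X - 1, 0, None), tissues)
        mods = self._modules_from(em)
        cors = cx.module_tissue_correlation(mods, em, "T")
        planted = mods.module_of("g1")
        assert planted != 0
        assert cors[planted] > 0.9

    def test_constant_indicator_returns_zero_with_warning(self, caplog):
        em, _ = simulate_block_expression(n_per_block=15, seed=2)
        mods = self._modules_from(em)
        with caplog.at_level("WARNING"):
            cors = cx.module_tissue_correlation(mods, em, "t1")  # every sample
        assert all(v == 0.0 for v in cors.values())
        assert "undefined" in caplog.text

    def test_unrelated_module_and_tissue_weakly_correlated(self):
        rng = np.random.default_rng(3)
        n = 100
        tissues = (["A"] * 50) + (["B"] * 50)
        factor = rng.normal(0, 1, n)  # tissue-agnostic latent factor
        X = np.tile(rng.uniform(1, 5, 50)[:, None], (1, n)) + factor[None, :]
        X += rng.normal(0, 0.3, X.shape)
        em = make_expression(np.clip(2.0**X - 1, 0, None), tissues)
        mods = self._modules_from(em)
        cors = cx.module_tissue_correlation(mods, em, "A")
        assert all(abs(v) < 0.5 for v in cors.values())
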