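import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mtxresponse.data import AlignmentError, ConfigError, ExpressionMatrix, PipelineError
from mtxresponse.network import (
    AdjacencyMatrix,
    ModuleAssignment,
    TOMatrix,
    adjacency,
    cluster_and_cut,
    connectivity,
    consensus_modules,
    consensus_tom,
    correlation_matrix,
    detect_group_specific_modules,
    hub_genes,
    module_overlap_test,
    soft_threshold,
    topological_overlap,
)


def expr_from(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i:03d}" for i in range(values.shape[0])],
                     columns=[f"s{j}" for j in range(values.shape[1])]),
        "normalized_log2",
    )


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop oracle for the unsigned TOM."""
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def hypergeom_tail_oracle(n_universe, m, n, k) -> float:
    """P(|A & B| >= k) by full enumeration of the n-subsets of the universe."""
    universe = list(range(n_universe))
    a = set(universe[:m])
    hits = total = 0
    for b in itertools.combinations(universe, n):
        total += 1
        hits += len(a & set(b)) >= k
    return hits / total


class TestCorrelation:
    def test_duplicate_and_negated_gene(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 10)
        m = expr_from(np.vstack([base, base, -base]))
        cor = correlation_matrix(m)
        assert cor.iloc[0, 1] == pytest.approx(1.0)
        assert cor.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_pairwise_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (5, 10))
        cor = correlation_matrix(expr_from(x)).to_numpy()
        for i in range(5):
            for j in range(5):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                direct = (xi @ xj) / math.sqrt((xi @ xi) * (xj @ xj))
                assert cor[i, j] == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_gene_named(self):
        x = np.vstack([np.ones(5), np.random.default_rng(2).normal(0, 1, 5)])
        with pytest.raises(PipelineError, match="g000"):
            correlation_matrix(expr_from(x))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            correlation_matrix(expr_from(np.random.default_rng(3).normal(0, 1, (4, 2))))


class TestAdjacency:
    def test_absolute_value_power(self):
        cor = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        adj = adjacency(cor, 2)
        assert adj.values[0, 1] == pytest.approx(0.25)
        assert adj.values[0, 0] == 0.0

    def test_beta_one_is_absolute_correlation(self):
        rng = np.random.default_rng(4)
        cor_vals = np.clip(rng.normal(0, 0.5, (4, 4)), -1, 1)
        cor_vals = (cor_vals + cor_vals.T) / 2
        np.fill_diagonal(cor_vals, 1.0)
        cor = pd.DataFrame(cor_vals)
        adj = adjacency(cor, 1)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(adj.values[off], np.abs(cor_vals)[off])

    def test_monotone_in_beta(self):
        rng = np.random.default_rng(5)
        cor_vals = np.clip(rng.uniform(-1, 1, (6, 6)), -1, 1)
        cor_vals = (cor_vals + cor_vals.T) / 2
        np.fill_diagonal(cor_vals, 1.0)
        cor = pd.DataFrame(cor_vals)
        low, high = adjacency(cor, 2).values, adjacency(cor, 5).values
        assert (high <= low + 1e-15).all()


class TestConnectivity:
    def test_row_sums(self):
        a = np.array([[0.0, 0.5, 0.2], [0.5, 0.0, 0.3], [0.2, 0.3, 0.0]])
        k = connectivity(AdjacencyMatrix(a, 1.0, ["a", "b", "c"]))
        np.testing.assert_allclose(k.values, [0.7, 0.8, 0.5])

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        perm = rng.permutation(8)
        k1 = connectivity(AdjacencyMatrix(a, 1.0, [f"g{i}" for i in range(8)]))
        k2 = connectivity(AdjacencyMatrix(a[np.ix_(perm, perm)], 1.0,
                                          [f"g{i}" for i in perm]))
        for g in k1.index:
            assert k1[g] == pytest.approx(k2[g])


class TestTopologicalOverlap:
    def test_three_gene_hand_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(AdjacencyMatrix(a, 1.0, ["a", "b", "c"]))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(tom.values[off], 0.5)
        np.testing.assert_allclose(np.diag(tom.values), 1.0)

    def test_zero_adjacency_gives_zero_tom(self):
        a = np.zeros((4, 4))
        tom = topological_overlap(AdjacencyMatrix(a, 1.0, list("abcd")))
        off = ~np.eye(4, dtype=bool)
        assert (tom.values[off] == 0).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = rng.integers(10, 25)
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = topological_overlap(AdjacencyMatrix(a, 1.0, [f"g{i}" for i in range(n)]))
            np.testing.assert_allclose(tom.values, tom_brute_force(a), atol=1e-10)


class TestSoftThreshold:
    def _cor(self, n_genes=60, n_samples=30, seed=8, hub_structure=True):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (n_genes, n_samples))
        if hub_structure:
            factor = rng.normal(0, 1, n_samples)
            loadings = rng.uniform(0.2, 1.5, n_genes)
            x += loadings[:, None] * factor[None, :]
        return correlation_matrix(expr_from(x))

    def test_singleton_grid_chosen(self):
        fit = soft_threshold(self._cor(), beta_grid=[6])
        assert fit.chosen_beta == 6.0

    def test_descending_grid_rejected(self):
        with pytest.raises(ConfigError):
            soft_threshold(self._cor(), beta_grid=[3, 2, 1])

    def test_degenerate_all_equal_correlations_falls_back(self, caplog):
        n = 30
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, 1.0)
        cor = pd.DataFrame(vals, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        with caplog.at_level("WARNING"):
            fit = soft_threshold(cor)
        assert not fit.met_target

    def test_r_squared_bounded(self):
        fit = soft_threshold(self._cor())
        r2 = fit.table["r_squared"].dropna()
        assert ((r2 >= 0) & (r2 <= 1)).all()


class TestClusterAndCut:
    def _two_block_tom(self, sizes=(60, 40), within=0.9, beta=6, seed=9):
        rng = np.random.default_rng(seed)
        n_samples = 50
        blocks = []
        for size, rho in zip(sizes, (within, within)):
            factor = rng.normal(0, 1, n_samples)
            loading = math.sqrt(rho / (1 - rho))
            blocks.append(loading * factor[None, :] + rng.normal(0, 1, (size, n_samples)))
        x = np.vstack(blocks)
        cor = correlation_matrix(expr_from(x))
        return topological_overlap(adjacency(cor, beta)), sizes

    def test_two_planted_blocks_recovered_exactly(self):
        tom, sizes = self._two_block_tom()
        assign, _ = cluster_and_cut(tom, min_module_size=30)
        labels = assign.labels
        assert len(assign.modules()) == 2
        block1 = set(labels.index[:sizes[0]])
        # the larger block gets the first color
        assert set(assign.members(assign.modules()[0])) == block1

    def test_min_module_size_respected(self):
        tom, _ = self._two_block_tom(sizes=(60, 40))
        assign, _ = cluster_and_cut(tom, min_module_size=50)
        sizes = assign.sizes()
        assert all(s >= 50 for m, s in sizes.items() if m != "grey")

    def test_min_size_larger_than_gene_count_rejected(self):
        tom, _ = self._two_block_tom(sizes=(10, 10))
        with pytest.raises(ConfigError):
            cluster_and_cut(tom, min_module_size=100)


class TestModuleOverlap:
    def _assignment(self, labels):
        return ModuleAssignment(pd.Series(labels, index=[f"g{i}" for i in range(len(labels))]))

    def test_identical_five_gene_modules(self):
        # N=10, m=n=5, full overlap: P = 1 / C(10,5)
        a = self._assignment(["m1"] * 5 + ["grey"] * 5)
        b = self._assignment(["x1"] * 5 + ["grey"] * 5)
        p = module_overlap_test(a, b).loc["m1", "x1"]
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        a = self._assignment(["m1"] * 5 + ["grey"] * 5)
        b = self._assignment(["grey"] * 5 + ["x1"] * 5)
        assert module_overlap_test(a, b).loc["m1", "x1"] == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self):
        for n_universe in (5, 8, 10):
            for m in (2, 3, n_universe // 2):
                for n in (2, n_universe // 2):
                    labels_a = ["m1"] * m + ["grey"] * (n_universe - m)
                    # B assigned so overlap with A's first m genes is max(m+n-N, ...)
                    labels_b = ["x1"] * n + ["grey"] * (n_universe - n)
                    a, b = self._assignment(labels_a), self._assignment(labels_b)
                    k = min(m, n)
                    p = module_overlap_test(a, b).loc["m1", "x1"]
                    assert p == pytest.approx(hypergeom_tail_oracle(n_universe, m, n, k), abs=1e-12)

    def test_universe_mismatch_rejected(self):
        a = self._assignment(["m1"] * 4)
        b = ModuleAssignment(pd.Series(["x1"] * 4, index=[f"h{i}" for i in range(4)]))
        with pytest.raises(AlignmentError):
            module_overlap_test(a, b)


class TestConsensus:
    def test_identical_groups_reproduce_single_group_modules(self):
        rng = np.random.default_rng(10)
        n_samples = 40
        factor = rng.normal(0, 1, n_samples)
        x = np.vstack([
            2.0 * factor[None, :] + rng.normal(0, 1, (50, n_samples)),
            rng.normal(0, 1, (50, n_samples)),
        ])
        m = expr_from(x)
        cons, groups = consensus_modules({"good": m, "nonresponder": m}, beta_grid=[6])
        pd.testing.assert_series_equal(cons.labels, groups["good"].labels)

    def test_consensus_tom_is_elementwise_lower_bound(self):
        rng = np.random.default_rng(11)
        toms = {}
        for g in ("a", "b"):
            v = rng.uniform(0, 0.5, (20, 20))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            toms[g] = TOMatrix(v, [f"g{i}" for i in range(20)])
        cons = consensus_tom(toms)
        off = ~np.eye(20, dtype=bool)
        q = {g: np.percentile(t.values[off], 95) for g, t in toms.items()}
        target = min(q.values())
        for g, t in toms.items():
            scaled = t.values * (target / q[g])
            assert (cons.values[off] <= scaled[off] + 1e-12).all()

    def test_group_specific_empty_when_assignments_identical(self):
        labels = pd.Series(["blue"] * 40 + ["grey"] * 10,
                           index=[f"g{i}" for i in range(50)])
        a = ModuleAssignment(labels.copy())
        b = ModuleAssignment(labels.copy())
        assert len(detect_group_specific_modules(a, b)) == 0

    def test_threshold_semantics_strict(self):
        group = ModuleAssignment(pd.Series(["blue"] * 10 + ["grey"] * 10,
                                           index=[f"g{i}" for i in range(20)]))
        # exactly half of the module is grey in consensus
        cons_labels = ["grey"] * 5 + ["other"] * 5 + ["grey"] * 10
        cons = ModuleAssignment(pd.Series(cons_labels, index=[f"g{i}" for i in range(20)]))
        assert len(detect_group_specific_modules(group, cons, grey_fraction_threshold=0.5)) == 0
        assert len(detect_group_specific_modules(group, cons, grey_fraction_threshold=0.49)) == 1


class TestHubGenes:
    def _assignment_and_k(self, sizes, k_values):
        labels, genes = [], []
        for idx, size in enumerate(sizes):
            for j in range(size):
                genes.append(f"g{idx}_{j:02d}")
                labels.append(f"mod{idx}")
        assign = ModuleAssignment(pd.Series(labels, index=genes))
        k = pd.Series(k_values, index=genes)
        return assign, k

    def test_top_20_percent_of_ten_is_two(self):
        assign, k = self._assignment_and_k([10], list(range(10)))
        hubs = hub_genes(assign, k, 0.20)
        assert len(hubs["mod0"]) == 2
        assert hubs["mod0"] == ["g0_09", "g0_08"]

    def test_ceiling_convention_small_module(self):
        assign, k = self._assignment_and_k([4], [1, 2, 3, 4])
        assert len(hub_genes(assign, k, 0.20)["mod0"]) == 1

    def test_ties_break_lexicographically(self):
        assign, k = self._assignment_and_k([5], [1.0] * 5)
        assert hub_genes(assign, k, 0.4)["mod0"] == ["g0_00", "g0_01"]

    def test_invalid_fraction_rejected(self):
        assign, k = self._assignment_and_k([5], [1.0] * 5)
        with pytest.raises(ConfigError):
            hub_genes(assign, k, 0.0)
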