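import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coreperiphery import (
    ContingencyTable,
    Partition,
    chi_squared,
    contingency,
    core_subgraph,
    cramers_v,
    louvain,
    reorder_diagonal,
    sample_control,
)
from coreperiphery.concordance import sample_nodes_by_strength


def manual_chi2_v(counts):
    """Independent cell-by-cell evaluation of X^2 and V."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    chi2 = 0.0
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            e = c[i].sum() * c[:, j].sum() / n
            chi2 += (c[i, j] - e) ** 2 / e
    v = np.sqrt((chi2 / n) / min(c.shape[0] - 1, c.shape[1] - 1))
    return chi2, v


class TestCoreSubgraph:
    def test_keeps_only_core_core_edges(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5)])
        sub = core_subgraph(g, {"A", "B", "D"})
        assert set(sub.edges) == {("A", "B")}
        assert "D" not in sub.nodes  # isolated core gene dropped

    def test_core_superset_is_identity(self, triangle):
        sub = core_subgraph(triangle, {"A", "B", "C", "Z"})
        assert set(sub.edges) == set(triangle.edges)

    def test_edgeless_result_rejected(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("A", "B", 0.5)])
        with pytest.raises(ValueError, match="no edges"):
            core_subgraph(g, {"A", "C"})


class TestContingency:
    def test_identical_partitions_diagonal(self):
        member = {f"n{i}": (0 if i < 12 else 1) for i in range(20)}
        p = Partition(membership=member)
        t = contingency(p, p)
        assert np.array_equal(t.counts, [[12, 0], [0, 8]])

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(5)
        a = Partition(membership={i: int(c) for i, c in enumerate(rng.integers(0, 4, 1000))})
        b = Partition(membership={i: int(c) for i, c in enumerate(rng.integers(0, 4, 1000))})
        t = contingency(a, b)
        # brute-force double loop
        expected = np.zeros((4, 4))
        for g in range(1000):
            expected[a.membership[g], b.membership[g]] += 1
        assert np.array_equal(t.counts, expected)
        assert t.counts.size == 16

    def test_disjoint_nodes_rejected(self):
        a = Partition(membership={"x": 0, "y": 1})
        b = Partition(membership={"z": 0, "w": 1})
        with pytest.raises(ValueError, match="share no nodes"):
            contingency(a, b)

    def test_unassigned_core_genes_excluded(self):
        a = Partition(membership={"x": 0, "y": 0, "z": 1, "w": 1})
        b = Partition(membership={"x": 0, "y": 1, "z": 0})
        t = contingency(a, b)
        assert t.n == 3


class TestReorderDiagonal:
    def test_swaps_columns(self):
        t = ContingencyTable.from_counts([[0, 12], [8, 0]])
        out = reorder_diagonal(t)
        assert np.array_equal(out.counts, [[12, 0], [0, 8]])
        assert out.col_labels == ("FC2", "FC1")

    def test_diagonal_fixed_point(self):
        t = ContingencyTable.from_counts([[12, 0], [0, 8]])
        assert np.array_equal(reorder_diagonal(t).counts, t.counts)

    def test_matches_exhaustive_permutation_search(self):
        rng = np.random.default_rng(11)
        c = rng.integers(0, 30, size=(4, 4)).astype(float)
        out = reorder_diagonal(ContingencyTable.from_counts(c))
        best = max(
            sum(c[i, perm[i]] for i in range(4))
            for perm in itertools.permutations(range(4))
        )
        assert np.trace(out.counts) == pytest.approx(best)
        # counts unchanged as a multiset of columns
        assert sorted(map(tuple, out.counts.T.tolist())) == sorted(map(tuple, c.T.tolist()))

    def test_surplus_columns_by_descending_sum(self):
        c = np.array([[10.0, 0.0, 3.0, 7.0], [0.0, 10.0, 2.0, 1.0]])
        out = reorder_diagonal(ContingencyTable.from_counts(c))
        assert np.array_equal(out.counts[:, :2], [[10, 0], [0, 10]])
        assert out.counts[:, 2].sum() >= out.counts[:, 3].sum()


class TestChiSquaredAndV:
    def test_independence_is_zero(self):
        t = ContingencyTable.from_counts([[5, 5], [5, 5]])
        assert chi_squared(t) == pytest.approx(0.0)
        assert cramers_v(t).v == pytest.approx(0.0)

    def test_diagonal_table(self):
        t = ContingencyTable.from_counts([[10, 0], [0, 10]])
        assert chi_squared(t) == pytest.approx(20.0)
        assert cramers_v(t).v == pytest.approx(1.0)

    def test_hand_evaluated_2x2(self):
        t = ContingencyTable.from_counts([[15, 22], [16, 91]])
        # closed form for 2x2: n (ad - bc)^2 / (r1 r2 c1 c2) = 10.65506
        assert chi_squared(t) == pytest.approx(144 * (15 * 91 - 22 * 16) ** 2 / (37 * 107 * 31 * 113), rel=1e-12)
        assert chi_squared(t) == pytest.approx(10.655, abs=0.001)
        assert cramers_v(t).v == pytest.approx(np.sqrt(10.655 / 144), abs=1e-4)
        assert cramers_v(t).v == pytest.approx(0.272, abs=0.001)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        c = rng.integers(1, 40, size=(3, 5)).astype(float)
        t = ContingencyTable.from_counts(c)
        chi2_scipy = stats.chi2_contingency(c, correction=False).statistic
        assert chi_squared(t) == pytest.approx(chi2_scipy, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_cellwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 7)), int(rng.integers(2, 7)))
        c = rng.integers(1, 50, size=shape).astype(float)
        t = ContingencyTable.from_counts(c)
        chi2_o, v_o = manual_chi2_v(c)
        res = cramers_v(t)
        assert res.chi2 == pytest.approx(chi2_o, rel=1e-12)
        assert res.v == pytest.approx(v_o, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_v_invariant_under_permutation_and_transpose(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
        c = rng.integers(1, 30, size=shape).astype(float)
        v0 = cramers_v(ContingencyTable.from_counts(c)).v
        rp = rng.permutation(shape[0])
        cp = rng.permutation(shape[1])
        assert cramers_v(ContingencyTable.from_counts(c[rp][:, cp])).v == pytest.approx(v0, rel=1e-10)
        assert cramers_v(ContingencyTable.from_counts(c.T)).v == pytest.approx(v0, rel=1e-10)
        assert 0.0 <= v0 <= 1.0

    def test_empty_rows_dropped_before_v(self):
        c = np.array([[10.0, 0.0], [0.0, 0.0], [0.0, 10.0]])
        res = cramers_v(ContingencyTable.from_counts(c))
        assert res.r == 2 and res.k == 2
        assert res.v == pytest.approx(1.0)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cramers_v(ContingencyTable.from_counts([[5.0, 5.0]]))


class TestSampling:
    def test_strength_weighted_single_draws(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.25)
        g.add_edge("b", "c", weight=0.5)
        # strengths: a 0.25, b 0.75, c 0.5 -> P(b) = 0.5
        rng = np.random.default_rng(0)
        hits = sum(sample_nodes_by_strength(g, 1, rng)[0] == "b" for _ in range(10000))
        assert hits / 10000 == pytest.approx(0.5, abs=0.02)

    def test_three_to_one_strength_ratio(self):
        # node 2 carries 3/4 of the total strength in its "half" of the graph:
        # strengths {1: 0.5, 0: 1.5, 2: 1.5, 3: 0.5} -> P(2) = 1.5/4 = 0.375
        g = nx.Graph()
        g.add_edge(1, 0, weight=0.5)
        g.add_edge(2, 0, weight=1.0)
        g.add_edge(2, 3, weight=0.5)
        rng = np.random.default_rng(1)
        draws = [sample_nodes_by_strength(g, 1, rng)[0] for _ in range(10000)]
        assert draws.count(2) / 10000 == pytest.approx(0.375, abs=0.02)

    @staticmethod
    def two_k6_bridge():
        g = nx.Graph()
        for base in (0, 6):
            for i in range(6):
                for j in range(i + 1, 6):
                    g.add_edge(base + i, base + j, weight=0.9)
        g.add_edge(5, 6, weight=0.05)
        return g

    def test_replicate_count(self):
        # size 8 of 12 guarantees >= 2 nodes per clique in every replicate
        g = self.two_k6_bridge()
        full = louvain(g, seed=0)
        ctrl = sample_control(g, size=8, seed=0, n_replicates=10, full_part=full)
        assert ctrl.n_replicates == 10
        assert len(ctrl.replicate_v) == 10
        assert min(ctrl.replicate_v) <= ctrl.mean_v <= max(ctrl.replicate_v)

    def test_full_size_sample_self_concordance(self, two_triangles_bridge):
        full = louvain(two_triangles_bridge, seed=0)
        ctrl = sample_control(
            two_triangles_bridge, size=6, seed=0, n_replicates=3, full_part=full
        )
        assert all(v == pytest.approx(1.0) for v in ctrl.replicate_v)
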