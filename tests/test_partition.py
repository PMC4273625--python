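import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import freqconn as fc
from freqconn.netbuild import AdjacencyMatrix

from conftest import er_graph, two_cliques


def twin_triangles():
    a = np.zeros((6, 6), int)
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1
    return a


class TestModularity:
    def test_single_community_is_zero(self):
        a = 1 - np.eye(4, dtype=int)
        assert fc.modularity(a, np.zeros(4, int)) == pytest.approx(0.0, abs=1e-12)

    def test_twin_triangles_components_give_half(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert fc.modularity(twin_triangles(), labels) == pytest.approx(0.5)

    def test_splitting_a_triangle_lowers_q(self):
        labels = np.array([0, 0, 2, 1, 1, 1])  # one triangle split
        assert fc.modularity(twin_triangles(), labels) < 0.5

    def test_edgeless_graph_is_fatal(self):
        with pytest.raises(ValueError, match="no"):
            fc.modularity(np.zeros((4, 4), int), np.zeros(4, int))

    def test_partition_must_cover_nodes(self):
        with pytest.raises(ValueError):
            fc.modularity(twin_triangles(), np.zeros(4, int))


class TestLouvain:
    def test_two_cliques_recovered_with_half_modularity(self):
        part = fc.louvain_partition(two_cliques(5), n_restarts=10, seed=0)
        assert part.n_communities == 2
        assert part.modularity_q == pytest.approx(0.5)
        labels = part.labels
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_complete_graph_is_one_community(self):
        part = fc.louvain_partition(1 - np.eye(6, dtype=int), n_restarts=10, seed=0)
        assert part.n_communities == 1
        assert part.modularity_q == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self):
        a = er_graph(25, 0.2, np.random.default_rng(1))
        p1 = fc.louvain_partition(a, n_restarts=5, seed=42)
        p2 = fc.louvain_partition(a, n_restarts=5, seed=42)
        assert np.array_equal(p1.labels, p2.labels)

    def test_all_zero_matrix_is_fatal(self):
        with pytest.raises(ValueError, match="zero"):
            fc.louvain_partition(np.zeros((5, 5)))

    def test_weighted_matrix_accepted(self):
        w = np.kron(np.eye(2), np.full((4, 4), 0.9)) - 0.9 * np.eye(8) + 0.05
        np.fill_diagonal(w, 0)
        part = fc.louvain_partition(w, n_restarts=10, seed=0)
        assert part.n_communities == 2


def exhaustive_best_modularity(a: np.ndarray) -> float:
    """Brute-force maximum of Q over all set partitions (oracle)."""

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [block + [first]] + part[i + 1 :]
            yield [[first]] + part

    n = a.shape[0]
    best = -np.inf
    labels = np.empty(n, int)
    for part in partitions(list(range(n))):
        for c, block in enumerate(part):
            labels[block] = c
        best = max(best, fc.modularity(a, labels))
    return best


class TestLouvainOracle:
    def test_small_example_attains_exhaustive_optimum(self):
        a = twin_triangles()
        assert fc.louvain_partition(a, n_restarts=10, seed=0).modularity_q == pytest.approx(
            exhaustive_best_modularity(a)
        )


class TestConsensus:
    def test_identical_partitions_give_binary_ca(self):
        p = fc.Partition(labels=np.array([0, 0, 1, 1, 2]))
        ca, group = fc.consensus_assignment([p, p, p], n_restarts=10, seed=0)
        assert set(np.unique(ca.values)) <= {0.0, 1.0}
        assert fc.nmi(group, p) == 1.0

    def test_orthogonal_splits_give_half_or_zero(self):
        p1 = fc.Partition(labels=np.array([0, 0, 1, 1]))
        p2 = fc.Partition(labels=np.array([0, 1, 0, 1]))
        ca, _ = fc.consensus_assignment([p1, p2], n_restarts=5, seed=0)
        # hand enumeration of the six pairs
        iu = np.triu_indices(4, 1)
        expected = {(0, 1): 0.5, (0, 2): 0.5, (0, 3): 0.0, (1, 2): 0.0, (1, 3): 0.5, (2, 3): 0.5}
        for i, j in zip(*iu):
            assert ca.values[i, j] == expected[(i, j)]

    def test_bounds_hold(self):
        rng = np.random.default_rng(2)
        parts = [fc.Partition(labels=rng.integers(0, 3, 12)) for _ in range(7)]
        ca, _ = fc.consensus_assignment(parts, n_restarts=5, seed=0)
        assert ca.values.min() >= 0 and ca.values.max() <= 1

    def test_mismatched_roi_sets_fatal(self):
        with pytest.raises(ValueError):
            fc.consensus_assignment(
                [fc.Partition(labels=np.zeros(4, int)), fc.Partition(labels=np.zeros(5, int))]
            )


class TestNMI:
    def test_self_similarity_is_exactly_one(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, 87)
        assert fc.nmi(labels, labels.copy()) == 1.0

    def test_orthogonal_four_node_partitions_share_nothing(self):
        assert fc.nmi(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])) == pytest.approx(0.0, abs=1e-12)

    def test_published_band_assignments_agree_to_059(self, roi_table):
        value = fc.nmi(roi_table["community_vlf"].to_numpy(), roi_table["community_lf"].to_numpy())
        assert round(value, 2) == 0.59

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            assert abs(fc.nmi(a, b) - fc.nmi(b, a)) < 1e-12

    def test_invariance_under_relabeling(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        remapped = np.array([{0: 7, 1: 2, 2: 11}[v] for v in b])
        assert fc.nmi(a, b) == pytest.approx(fc.nmi(a, remapped), abs=1e-12)

    def test_degenerate_single_community_cases(self):
        ones = np.zeros(6, int)
        split = np.array([0, 0, 0, 1, 1, 1])
        assert fc.nmi(ones, ones) == 1.0
        assert fc.nmi(ones, split) == 0.0
        assert fc.nmi(split, ones) == 0.0

    def test_mismatched_lengths_fatal(self):
        with pytest.raises(ValueError):
            fc.nmi(np.zeros(4, int), np.zeros(5, int))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_bounded_and_symmetric_on_arbitrary_labelings(self, data):
        n = data.draw(st.integers(2, 40))
        a = np.array(data.draw(st.lists(st.integers(0, 4), min_size=n, max_size=n)))
        b = np.array(data.draw(st.lists(st.integers(0, 4), min_size=n, max_size=n)))
        value = fc.nmi(a, b)
        assert 0.0 <= value <= 1.0
        assert abs(value - fc.nmi(b, a)) < 1e-12


def planted_adjacency(labels, p_in, p_out, rng):
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    probs = np.where(same, p_in, p_out)
    a = (rng.random((n, n)) < probs).astype(int)
    a = np.triu(a, 1)
    return a + a.T


class TestNMISignificance:
    def test_default_null_count(self):
        import inspect

        assert inspect.signature(fc.nmi_significance).parameters["n_null"].default == 10_000

    def test_shared_planted_structure_is_significant(self):
        """Two networks from one strong 3-block partition: the NMI between
        their detected communities beats every degree-preserving null."""
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1, 2], 20)
        a1 = AdjacencyMatrix(values=planted_adjacency(labels, 0.7, 0.05, rng))
        a2 = AdjacencyMatrix(values=planted_adjacency(labels, 0.7, 0.05, rng))
        res = fc.nmi_significance(a1, a2, n_null=1000, seed=0)
        assert res.nmi > 0.9
        assert res.p_value <= 0.001

    def test_independent_random_graphs_are_not_significant(self):
        rng = np.random.default_rng(7)
        ps = []
        for s in range(9):
            a1 = AdjacencyMatrix(values=er_graph(40, 0.2, rng))
            a2 = AdjacencyMatrix(values=er_graph(40, 0.2, rng))
            ps.append(fc.nmi_significance(a1, a2, n_null=199, seed=s).p_value)
        assert np.median(ps) > 0.05

    def test_external_reference_returns_conservative_p(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([0, 1, 2], 15)
        ag = AdjacencyMatrix(values=planted_adjacency(labels, 0.7, 0.05, rng))
        res = fc.nmi_significance(ag, fc.Partition(labels=labels), n_null=199, seed=0)
        assert set(res.p_values) == {"rewired", "random"}
        assert res.p_value == max(res.p_values.values())
        assert res.p_value < 0.05
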