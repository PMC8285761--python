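"""Soft assignments, pooled graphs, and the nerve/matrix equivalence."""

import itertools

import numpy as np
import pytest

from graphmapper import (
    AttributedGraph,
    LensValues,
    SoftAssignment,
    assignment_to_nerve,
    dmp_assignment,
    fixtures,
    hierarchical_pool,
    make_rbf_cover,
    mpr_assignment,
    pool,
)

from conftest import random_graph


def random_soft_assignment(rng, n, k, sparsity=0.0) -> SoftAssignment:
    """Random row-stochastic matrix with a controlled zero fraction."""
    s = rng.uniform(0.0, 1.0, size=(n, k))
    mask = rng.random((n, k)) < sparsity
    s[mask] = 0.0
    for row in s:
        if row.sum() == 0:
            row[rng.integers(k)] = 1.0
    return SoftAssignment(s / s.sum(axis=1, keepdims=True))


class TestSoftAssignmentInvariants:
    def test_rows_must_be_stochastic(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SoftAssignment(np.array([[0.5, 0.4]]))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SoftAssignment(np.array([[1.5, -0.5]]))


class TestMPR:
    def test_rows_sum_to_one_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            g = random_graph(rng, n_max=25)
            S = mpr_assignment(g, int(rng.integers(1, 8)), float(rng.uniform(0, 0.5)))
            assert np.abs(S.matrix.sum(axis=1) - 1.0).max() < 1e-9

    def test_overlap_nodes_split_mass_evenly(self):
        # star graph: hub lens value 1, leaves 0; any node strictly inside
        # exactly one element is one-hot
        g = fixtures.standard_graphs("star", 6)
        S = mpr_assignment(g, 3, 0.2)
        for row in S.matrix:
            nz = row[row > 0]
            assert np.allclose(nz, 1.0 / nz.size)

    def test_ring_uniform_pagerank_identical_rows(self, ring4):
        S = mpr_assignment(ring4, 4, 0.1)
        assert np.allclose(S.matrix, S.matrix[0])

    def test_empty_columns_dropped_with_map(self, ring4):
        S = mpr_assignment(ring4, 5, 0.0)
        assert S.n_clusters == 1  # constant lens lands in one element
        assert len(S.provenance["kept_columns"]) == S.n_clusters


class TestDMP:
    def test_single_kernel_all_ones_column(self):
        lens = LensValues(np.linspace(-3, 3, 7))
        S = dmp_assignment(lens, make_rbf_cover(1))
        assert np.allclose(S.matrix, 1.0)

    def test_huge_scale_gives_uniform_rows(self):
        lens = LensValues(np.linspace(-2, 2, 9))
        S = dmp_assignment(lens, make_rbf_cover(4, scale_delta=1e6))
        assert np.abs(S.matrix - 0.25).max() < 1e-6

    def test_tiny_scale_concentrates_on_nearest_center(self):
        cover = make_rbf_cover(5, scale_delta=0.002)
        # pick lens values whose sigmoid lands exactly on a center
        z_target = cover.centers[2]  # 0.5 -> logit 0
        lens = LensValues(np.array([0.0]))
        S = dmp_assignment(lens, cover)
        assert S.matrix[0, 2] > 0.99

    def test_rows_sum_exactly_one(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            lens = LensValues(rng.normal(size=rng.integers(1, 30)))
            cover = make_rbf_cover(int(rng.integers(1, 10)))
            S = dmp_assignment(lens, cover)
            assert np.abs(S.matrix.sum(axis=1) - 1.0).max() < 1e-12

    def test_underflow_floored_with_warning(self):
        lens = LensValues(np.array([50.0]))  # sigmoid ~ 1, far from center 0
        cover = make_rbf_cover(1, scale_delta=1e-8)
        cover.centers = np.array([0.0])
        with pytest.warns(UserWarning, match="underflow"):
            S = dmp_assignment(lens, cover)
        assert np.allclose(S.matrix.sum(axis=1), 1.0)

    def test_mean_row_entropy_decreases_with_scale(self):
        """The low-entropy property: sharper kernels give sharper rows."""
        rng = np.random.default_rng(8)
        lens = LensValues(rng.uniform(-1, 1, 40))
        entropies = []
        for delta in (10.0, 1.0, 0.1, 0.01, 0.001):
            S = dmp_assignment(lens, make_rbf_cover(6, scale_delta=delta))
            p = np.clip(S.matrix, 1e-300, None)
            entropies.append(float((-p * np.log(p)).sum(axis=1).mean()))
        assert all(a >= b - 1e-12 for a, b in zip(entropies, entropies[1:]))


class TestPool:
    def test_identity_assignment_recovers_a_plus_i(self, path3):
        S = SoftAssignment(np.eye(3))
        pg = pool(S, path3)
        expected = path3.adjacency.toarray() + np.eye(3)
        assert np.allclose(pg.adjacency, expected)
        assert np.allclose(pg.features, path3.features)

    def test_hand_computed_two_cluster_path(self, path3):
        S = SoftAssignment(np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]))
        pg = pool(S, path3)
        assert np.allclose(pg.adjacency, [[1.0, 1.0], [1.0, 4.0]])

    def test_clusters_in_different_components_disconnected(self):
        g = AttributedGraph.from_edges(4, [(0, 1), (2, 3)])
        S = SoftAssignment(
            np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
        )
        pg = pool(S, g)
        assert pg.adjacency[0, 1] == 0.0 and pg.adjacency[1, 0] == 0.0

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = random_graph(rng, n_max=15)
            S = random_soft_assignment(rng, g.n_nodes, 4, sparsity=0.4)
            pg = pool(S, g)
            assert np.allclose(pg.adjacency, pg.adjacency.T, atol=1e-12)

    def test_feature_mass_conservation(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng, n_max=20)
        g.features = rng.normal(size=(g.n_nodes, 3))
        S = random_soft_assignment(rng, g.n_nodes, 5)
        pg = pool(S, g)
        assert np.allclose(pg.features.sum(axis=0), g.features.sum(axis=0), atol=1e-9)

    def test_shape_mismatch_rejected(self, path3):
        with pytest.raises(ValueError):
            pool(SoftAssignment(np.ones((5, 1))), path3)


class TestNerveEquivalence:
    """The soft-assignment nerve matches the matrix product pattern."""

    @staticmethod
    def brute_force_pattern(S: np.ndarray, a_hat: np.ndarray) -> set:
        """Independent oracle: set intersections over nodes and edges."""
        k = S.shape[1]
        members = [set(np.flatnonzero(S[:, j] > 0).tolist()) for j in range(k)]
        n = a_hat.shape[0]
        edges_of = [
            {
                (min(u, v), max(u, v))
                for u in range(n)
                for v in range(n)
                if a_hat[u, v] != 0 and (u in m or v in m)
            }
            for m in members
        ]
        out = set()
        for i, j in itertools.combinations(range(k), 2):
            if members[i] & members[j] or edges_of[i] & edges_of[j]:
                out.add((i, j))
        return out

    def test_hard_one_hot_assignment_pullback(self, path3):
        S = SoftAssignment(np.array([[1.0, 0], [0, 1.0], [0, 1.0]]))
        summary = assignment_to_nerve(S, path3)
        assert [sorted(c.nodes) for c in summary.clusters] == [[0], [1, 2]]

    def test_strictly_positive_assignment_complete_nerve(self, ring4):
        S = SoftAssignment(np.full((4, 3), 1.0 / 3.0))
        summary = assignment_to_nerve(S, ring4)
        assert summary.edge_set() == {(0, 1), (0, 2), (1, 2)}

    def test_matrix_pattern_equals_nerve_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            g = random_graph(rng, n_max=15, p=0.3)
            k = int(rng.integers(1, 6))
            S = random_soft_assignment(
                rng, g.n_nodes, k, sparsity=float(rng.uniform(0.0, 0.8))
            )
            pooled = pool(S, g)
            off = pooled.adjacency.copy()
            np.fill_diagonal(off, 0.0)
            pattern = {
                (i, j)
                for i in range(k)
                for j in range(i + 1, k)
                if abs(off[i, j]) > 1e-12
            }
            nerve = assignment_to_nerve(S, g)
            cols = nerve.provenance["columns"]
            nerve_edges = {
                tuple(sorted((cols[a], cols[b]))) for a, b in nerve.edge_set()
            }
            assert pattern == nerve_edges
            a_hat = g.adjacency.toarray() + np.eye(g.n_nodes)
            assert pattern == self.brute_force_pattern(S.matrix, a_hat)

    def test_shared_edge_criterion_exhaustive_on_four_nodes(self):
        """Over all labeled 4-node graphs and hard 2-partitions, the pooled
        adjacency is nonzero exactly when the parts share an edge of A+I."""
        pairs = list(itertools.combinations(range(4), 2))
        for bits in range(64):
            edges = [pairs[i] for i in range(6) if bits >> i & 1]
            g = AttributedGraph.from_edges(4, edges)
            a_hat = g.adjacency.toarray() + np.eye(4)
            for assign_bits in range(1, 15):  # both parts nonempty
                part = [(assign_bits >> v) & 1 for v in range(4)]
                S = SoftAssignment(np.eye(2)[part])
                pg = pool(S, g)
                shares_edge = any(
                    a_hat[u, v] != 0
                    for u in range(4)
                    for v in range(4)
                    if part[u] == 0 and part[v] == 1
                )
                assert (pg.adjacency[0, 1] != 0) == shares_edge


class TestHierarchicalPool:
    def test_schedule_respects_cover_sizes(self):
        g = fixtures.spammer_graph(n_spam=10, n_normal=90, seed=1)
        levels = hierarchical_pool(g, method="mpr", cover_sizes=(20, 5), overlap=0.25)
        assert len(levels) == 2
        assert levels[0].n_nodes <= 20
        assert levels[1].n_nodes <= 5
        assert levels[1].n_nodes < levels[0].n_nodes

    def test_pool_to_single_node_closed_form(self, path3):
        (level,) = hierarchical_pool(path3, cover_sizes=(1,))
        a_hat = path3.adjacency.toarray() + np.eye(3)
        assert level.adjacency.shape == (1, 1)
        assert level.adjacency[0, 0] == pytest.approx(a_hat.sum())

    def test_permutation_assignment_isomorphic_to_a_plus_i(self):
        """One cluster per node (disjoint cover, injective lens) just
        permutes A+I."""
        rng = np.random.default_rng(17)
        g = random_graph(rng, n_max=12)
        perm = rng.permutation(g.n_nodes)
        S = SoftAssignment(np.eye(g.n_nodes)[perm])
        pg = pool(S, g)
        a_hat = g.adjacency.toarray() + np.eye(g.n_nodes)
        inv = np.argsort(perm)
        assert np.allclose(pg.adjacency, a_hat[np.ix_(inv, inv)])

    def test_oversized_level_skipped_with_warning(self, path3):
        with pytest.warns(UserWarning, match="skipping"):
            levels = hierarchical_pool(path3, cover_sizes=(10, 2), overlap=0.0)
        assert len(levels) == 1

    def test_dmp_schedule_runs(self):
        g = fixtures.spammer_graph(n_spam=5, n_normal=45, seed=2)
        levels = hierarchical_pool(g, method="dmp", cover_sizes=(8, 2))
        assert [l.n_nodes for l in levels] == [8, 2]
        for level in levels:
            assert np.allclose(level.assignment.matrix.sum(axis=1), 1.0)
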