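"""GCN forward pass, readout, full classifier and the training demo."""

import numpy as np
import pytest

from graphmapper import (
    AttributedGraph,
    ClassifierParams,
    GCNLayerParams,
    SoftAssignment,
    TrainConfig,
    classify_graph,
    fixtures,
    gcn_forward,
    readout_classify,
    train_demo,
)
from graphmapper.gnn import normalized_adjacency

from conftest import random_graph


def naive_gcn_oracle(X, A, W, relu=True):
    """Direct dense evaluation of the convolution rule."""
    a_hat = np.asarray(A, dtype=float) + np.eye(A.shape[0])
    d = np.diag(1.0 / np.sqrt(a_hat.sum(axis=1)))
    out = d @ a_hat @ d @ X @ W
    return np.maximum(out, 0) if relu else out


class TestGCNForward:
    def test_edgeless_graph_reduces_to_activation(self):
        g = AttributedGraph.from_edges(3, [])
        X = np.array([[-1.0], [0.5], [2.0]])
        out = gcn_forward(X, g.adjacency, GCNLayerParams(np.eye(1), "relu"))
        assert np.allclose(out, np.maximum(X, 0))

    def test_single_edge_hand_evaluation(self):
        g = AttributedGraph.from_edges(2, [(0, 1)])
        X = np.array([[1.0], [0.0]])
        out = gcn_forward(X, g.adjacency, GCNLayerParams(np.eye(1), "identity"))
        assert np.allclose(out, [[0.5], [0.5]])

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = random_graph(rng, n_max=20)
            X = rng.normal(size=(g.n_nodes, int(rng.integers(1, 5))))
            W = rng.normal(size=(X.shape[1], int(rng.integers(1, 5))))
            out = gcn_forward(X, g.adjacency, GCNLayerParams(W, "relu"))
            assert np.abs(out - naive_gcn_oracle(X, g.adjacency.toarray(), W)).max() < 1e-10

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, n_max=12)
        X = rng.normal(size=(g.n_nodes, 3))
        W = rng.normal(size=(3, 2))
        perm = rng.permutation(g.n_nodes)
        edges = [(int(perm[u]), int(perm[v])) for u, v in g.edges()]
        g_perm = AttributedGraph.from_edges(g.n_nodes, edges)
        out = gcn_forward(X, g.adjacency, GCNLayerParams(W))
        out_perm = gcn_forward(X[np.argsort(perm)], g_perm.adjacency, GCNLayerParams(W))
        assert np.allclose(out_perm[perm], out, atol=1e-12)

    def test_weighted_adjacency_accepted(self):
        a = np.array([[0.0, 2.0], [2.0, 0.0]])
        m = normalized_adjacency(a)
        assert np.allclose(m, m.T)
        assert np.allclose(m.sum(), (np.ones(2) @ m @ np.ones(2)))


class TestReadout:
    def test_zero_weights_uniform_probabilities(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        probs = readout_classify(X, np.zeros((3, 4)), np.zeros(4))
        assert np.allclose(probs, 0.25)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        probs = readout_classify(
            rng.normal(size=(7, 4)), rng.normal(size=(4, 3)), rng.normal(size=3)
        )
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_node_duplication_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 3))
        Wf, bf = rng.normal(size=(3, 2)), rng.normal(size=2)
        assert np.allclose(
            readout_classify(X, Wf, bf),
            readout_classify(np.vstack([X, X]), Wf, bf),
            atol=1e-12,
        )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            readout_classify(np.zeros((0, 2)), np.zeros((2, 2)), np.zeros(2))


def small_params(in_dim=2, seed=0):
    return ClassifierParams.glorot_init(in_dim, (8, 8), (8,), 2, seed=seed)


class TestClassifyGraph:
    def test_probability_vector_valid(self):
        g = fixtures.standard_graphs("ring", 12)
        probs = classify_graph(g, small_params())
        assert probs.shape == (2,)
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_pool_to_single_cluster_matches_manual_composition(self):
        g = fixtures.standard_graphs("ring", 8)
        params = ClassifierParams.glorot_init(2, (8,), (), 2, seed=1)
        S = SoftAssignment(np.full((8, 1), 1.0))
        probs = classify_graph(g, params, cover_sizes=(1,), assignments=[S])
        x = gcn_forward(g.features, g.adjacency, params.embed_layers[0])
        pooled = S.matrix.T @ x
        expected = readout_classify(pooled, params.readout_weight, params.readout_bias)
        assert np.allclose(probs, expected, atol=1e-12)

    def test_isomorphic_graphs_identical_probabilities(self):
        rng = np.random.default_rng(5)
        g = fixtures.standard_graphs("sbm", (6, 6), seed=4, p_in=0.9, p_out=0.2)
        perm = rng.permutation(g.n_nodes)
        edges = [(int(perm[u]), int(perm[v])) for u, v in g.edges()]
        g_perm = AttributedGraph.from_edges(g.n_nodes, edges)
        g_perm.features = g.features[np.argsort(perm)]
        params = small_params()
        assert np.allclose(
            classify_graph(g, params), classify_graph(g_perm, params), atol=1e-10
        )

    def test_identity_pooling_equals_deeper_gcn(self):
        """With S = I, pooling only renormalizes self-loops; the forward
        pass equals an explicit layer-by-layer evaluation."""
        g = fixtures.standard_graphs("path", 6)
        params = small_params(seed=2)
        S = SoftAssignment(np.eye(6))
        probs = classify_graph(g, params, cover_sizes=(6,), assignments=[S])
        x = g.features
        for layer in params.embed_layers:
            x = gcn_forward(x, g.adjacency, layer)
        a_pooled = g.adjacency.toarray() + np.eye(6)  # A' = A + I
        for layer in params.classify_layers:
            x = gcn_forward(x, a_pooled, layer)
        expected = readout_classify(x, params.readout_weight, params.readout_bias)
        assert np.allclose(probs, expected, atol=1e-10)


class TestParamsIO:
    def test_json_round_trip(self, tmp_path):
        params = small_params(seed=7)
        path = params.to_json(tmp_path / "model.json")
        loaded = ClassifierParams.from_json(path)
        for a, b in zip(params.embed_layers, loaded.embed_layers):
            assert np.array_equal(a.weight, b.weight)
            assert a.activation == b.activation
        assert np.array_equal(params.readout_weight, loaded.readout_weight)

    def test_dimension_chain_validated(self):
        with pytest.raises(ValueError, match="chain"):
            ClassifierParams(
                embed_layers=[GCNLayerParams(np.ones((2, 3)))],
                classify_layers=[GCNLayerParams(np.ones((4, 2)))],
                readout_weight=np.ones((2, 2)),
                readout_bias=np.zeros(2),
            )


class TestTrainDemo:
    def test_gradients_match_finite_differences(self):
        """The hand-written reverse pass agrees with numerical gradients."""
        from graphmapper.gnn import _backward, _flatten_params, _prepare

        g = fixtures.standard_graphs("sbm", (4, 4), seed=0, p_in=0.9, p_out=0.2)
        params = ClassifierParams.glorot_init(2, (3,), (3,), 2, seed=0)
        prep = _prepare(g, (2, 1), 0.25)
        _, grads = _backward(prep, params, 1)
        flat = _flatten_params(params)
        eps = 1e-6
        from graphmapper.gnn import _forward

        def loss_fn():
            probs = _forward(prep, params)
            return -float(np.log(probs[1]))

        rng = np.random.default_rng(0)
        for p, gr in zip(flat, grads):
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                up = loss_fn()
                p[idx] = orig - eps
                down = loss_fn()
                p[idx] = orig
                assert gr[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-4)

    def test_learns_synthetic_two_class_task(self):
        dataset = fixtures.classification_dataset(60, seed=0)
        params, history = train_demo(dataset, TrainConfig(seed=0))
        assert len(history["train_acc"]) <= 30
        assert max(history["train_acc"]) >= 0.9

    def test_epoch_cap_honored(self):
        dataset = fixtures.classification_dataset(20, seed=1)
        _, history = train_demo(
            dataset, TrainConfig(max_epochs=3, patience=100, seed=1)
        )
        assert len(history["train_acc"]) == 3

    def test_zero_features_stay_at_chance(self):
        dataset = fixtures.classification_dataset(40, seed=2)
        for g in dataset.graphs:
            g.features = np.zeros((g.n_nodes, 1))  # no signal at all
        _, history = train_demo(dataset, TrainConfig(max_epochs=10, seed=2))
        # balanced two-class data with zero features: chance-level accuracy
        assert history["train_acc"][-1] <= 0.65

    def test_determinism_under_seed(self):
        dataset = fixtures.classification_dataset(20, seed=3)
        _, h1 = train_demo(dataset, TrainConfig(max_epochs=5, seed=3))
        _, h2 = train_demo(dataset, TrainConfig(max_epochs=5, seed=3))
        assert h1["train_acc"] == h2["train_acc"]
        assert h1["train_loss"] == h2["train_loss"]
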