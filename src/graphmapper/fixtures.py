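"""Seeded synthetic-graph generators with known ground truth.

These give every other module a deterministic, fully in-memory input:

* :func:`spammer_graph` — a two-population network: a small set of
  "spammers" wired indiscriminately to everyone, and "normal" users that
  only connect within small communities.  Emulates the hub-vs-community
  structure of abuse networks, with binary node labels.
* :func:`standard_graphs` — rings, paths, stars, barbells, stochastic
  block models and Erdos-Renyi graphs, the standard substrates for
  spectral and nerve properties.
* :func:`classification_dataset` — a balanced two-class graph dataset
  (rings vs 2-block SBMs of matched size) that is easy enough to learn
  at desk scale yet not linearly trivial from raw counts alone.

Every generator consumes one integer seed driving a dedicated
``numpy.random.Generator``; no global random state is touched.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .graph_io import AttributedGraph, GraphDataset

__all__ = [
    "spammer_graph",
    "standard_graphs",
    "classification_dataset",
]


def _degree_features(adjacency: sp.csr_matrix, rng=None, noise_dim: int = 0):
    binary = adjacency.copy()
    if binary.nnz:
        binary.data = np.ones_like(binary.data)
    deg = np.asarray(binary.sum(axis=1)).ravel()
    if noise_dim and rng is not None:
        onehot = np.zeros((deg.size, noise_dim))
        onehot[np.arange(deg.size), rng.integers(0, noise_dim, deg.size)] = 1.0
        return np.column_stack([np.ones_like(deg), deg, onehot])
    return np.column_stack([np.ones_like(deg), deg])


def spammer_graph(
    n_spam: int = 20,
    n_normal: int = 180,
    p_spam: float = 0.3,
    p_comm: float = 0.2,
    n_communities: int = 15,
    seed: int = 0,
) -> AttributedGraph:
    """Spammer/non-spammer network with binary labels (1 = spammer).

    Spammers connect to *any* node with probability ``p_spam``;
    non-spammers connect only inside their community (communities
    partition the normal users round-robin) with probability ``p_comm``.
    With the default sizes spammers end up far better connected than
    normal users.  Node features are a constant column, the degree, and
    a small one-hot noise block.
    """
    if n_spam < 1 or n_normal < 1:
        raise ValueError("both classes must be nonempty")
    if p_spam <= p_comm:
        warnings.warn(
            "p_spam <= p_comm: spammers may not be better connected than "
            "community members"
        )
    rng = np.random.default_rng(seed)
    n = n_spam + n_normal
    community = np.full(n, -1)
    community[n_spam:] = np.arange(n_normal) % n_communities
    rows, cols = [], []
    for u in range(n):
        for v in range(u + 1, n):
            if u < n_spam or v < n_spam:
                p = p_spam
            elif community[u] == community[v]:
                p = p_comm
            else:
                continue
            if rng.random() < p:
                rows += [u, v]
                cols += [v, u]
    a = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    labels = np.zeros(n, dtype=int)
    labels[:n_spam] = 1
    feats = _degree_features(a, rng=rng, noise_dim=4)
    return AttributedGraph(
        a, features=feats, labels=labels, name=f"spammer(seed={seed})"
    )


def standard_graphs(kind: str, sizes, seed: int = 0, **kwargs) -> AttributedGraph:
    """Deterministic standard constructions.

    ``kind`` is one of ``ring``, ``path``, ``star``, ``barbell``,
    ``sbm``, ``random_gnp``.  ``sizes`` is an int (ring/path/star: node
    count; star: leaf count) or a tuple (barbell: the two clique sizes;
    sbm: block sizes).  SBM takes ``p_in``/``p_out`` keywords, G(n, p)
    takes ``p``.
    """
    rng = np.random.default_rng(seed)
    if kind == "ring":
        n = int(sizes)
        if n < 3:
            raise ValueError("ring needs >= 3 nodes")
        edges = [(i, (i + 1) % n) for i in range(n)]
        return _from_edges(n, edges, f"ring({n})")
    if kind == "path":
        n = int(sizes)
        if n < 1:
            raise ValueError("path needs >= 1 node")
        edges = [(i, i + 1) for i in range(n - 1)]
        return _from_edges(n, edges, f"path({n})")
    if kind == "star":
        k = int(sizes)
        if k < 1:
            raise ValueError("star needs >= 1 leaf")
        edges = [(0, i) for i in range(1, k + 1)]
        return _from_edges(k + 1, edges, f"star({k})")
    if kind == "barbell":
        m1, m2 = (int(sizes[0]), int(sizes[1]))
        if m1 < 2 or m2 < 2:
            raise ValueError("barbell cliques need >= 2 nodes each")
        edges = [(i, j) for i in range(m1) for j in range(i + 1, m1)]
        edges += [
            (m1 + i, m1 + j) for i in range(m2) for j in range(i + 1, m2)
        ]
        edges.append((m1 - 1, m1))  # the bridge
        return _from_edges(m1 + m2, edges, f"barbell({m1},{m2})")
    if kind == "sbm":
        block_sizes = [int(s) for s in sizes]
        p_in = float(kwargs.get("p_in", 0.9))
        p_out = float(kwargs.get("p_out", 0.05))
        n = sum(block_sizes)
        block = np.repeat(np.arange(len(block_sizes)), block_sizes)
        edges = []
        for u in range(n):
            for v in range(u + 1, n):
                p = p_in if block[u] == block[v] else p_out
                if rng.random() < p:
                    edges.append((u, v))
        g = _from_edges(n, edges, f"sbm({block_sizes},seed={seed})")
        g.labels = block.astype(int)
        return g
    if kind == "random_gnp":
        n = int(sizes)
        p = float(kwargs.get("p", 0.3))
        edges = [
            (u, v)
            for u in range(n)
            for v in range(u + 1, n)
            if rng.random() < p
        ]
        return _from_edges(n, edges, f"gnp({n},{p},seed={seed})")
    raise ValueError(f"unknown graph kind {kind!r}")


def _from_edges(n: int, edges, name: str) -> AttributedGraph:
    g = AttributedGraph.from_edges(n, edges, name=name)
    g.features = _degree_features(g.adjacency)
    return g


def classification_dataset(n_graphs: int = 100, seed: int = 0) -> GraphDataset:
    """Balanced two-class dataset: rings (class 0) vs 2-block SBMs (class 1).

    Sizes are drawn uniformly in 10..20 and matched across classes; SBMs
    use ``p_in = 0.8``, ``p_out = 0.1``.  Features are a constant column
    plus the node degree, which makes the classes separable through
    degree statistics while exercising the full embed-pool-classify
    pipeline.
    """
    if n_graphs % 2:
        raise ValueError("n_graphs must be even for balanced classes")
    rng = np.random.default_rng(seed)
    graphs: list[AttributedGraph] = []
    labels: list[int] = []
    for i in range(n_graphs // 2):
        n = int(rng.integers(10, 21))
        graphs.append(standard_graphs("ring", n, seed=int(rng.integers(2**31))))
        labels.append(0)
        half = n // 2
        sbm = standard_graphs(
            "sbm",
            (half, n - half),
            seed=int(rng.integers(2**31)),
            p_in=0.8,
            p_out=0.1,
        )
        sbm.labels = None  # graph-level task: node labels unused
        graphs.append(sbm)
        labels.append(1)
    order = rng.permutation(n_graphs)
    graphs = [graphs[i] for i in order]
    labels = [labels[i] for i in order]
    return GraphDataset(graphs=graphs, graph_labels=np.array(labels), split_seed=seed)
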