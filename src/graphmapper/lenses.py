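"""Lens functions ``f: V -> R^d`` (d in {1, 2}) that parameterize graph nodes.

A lens drives the Mapper decomposition: nodes with nearby lens values fall
into the same cover elements and hence the same summary clusters.  Built-in
lenses:

* :func:`pagerank_lens` — stationary random-walk importance (power
  iteration with teleport), min-max rescaled to span ``[0, 1]``.
* :func:`fiedler_lens` — the Fiedler vector (Laplacian eigenvector of the
  second-smallest eigenvalue), whose sign pattern gives a spectral
  bipartition.
* :func:`density_lens` — a smoothed closeness measure
  ``f(v) = sum_u exp(-D(u, v) / scale)`` over hop distances.
* :func:`embedding_lens` — precomputed node embeddings passed through a
  pluggable dimensionality reducer (identity, PCA, t-SNE, ...).
* :func:`supervised_prob_lens` — a binary classifier's positive-class
  probability per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.csgraph import shortest_path

from .graph_io import AttributedGraph

__all__ = [
    "LensValues",
    "pagerank_lens",
    "fiedler_lens",
    "density_lens",
    "embedding_lens",
    "supervised_prob_lens",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LensValues:
    """Per-node lens coordinates, shape ``(N, d)`` with ``d`` in {1, 2}."""

    values: np.ndarray
    lens_name: str = "lens"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[1] not in (1, 2):
            raise ValueError(f"lens values must be N x d with d in {{1,2}}, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("lens values contain NaN/Inf")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    @property
    def range(self) -> list[tuple[float, float]]:
        return [
            (float(self.values[:, j].min()), float(self.values[:, j].max()))
            for j in range(self.dim)
        ]

    def column(self, j: int = 0) -> np.ndarray:
        return self.values[:, j]


def _transition_matrix(g: AttributedGraph) -> sp.csr_matrix:
    """Row-stochastic random-walk matrix; dangling rows left all-zero."""
    a = g.adjacency
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return sp.diags(inv) @ a


def pagerank_lens(
    g: AttributedGraph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
    rescale: bool = True,
) -> LensValues:
    """PageRank importance of every node, rescaled to ``[0, 1]``.

    The undirected graph is treated as bidirected; edge weights feed the
    transition probabilities.  Dangling (isolated) nodes redistribute
    their mass uniformly, which keeps the chain stochastic.  The raw
    stationary vector sums to one; the returned lens is min-max rescaled
    so the interval cover over ``[0, 1]`` is fully used (a constant raw
    vector maps to the midpoint 0.5).  The raw scores are kept in
    ``metadata["raw"]``.
    """
    n = g.n_nodes
    if n == 0:
        raise ValueError("PageRank undefined on the empty graph")
    if not (0.0 < damping < 1.0):
        raise ValueError("damping must lie strictly between 0 and 1")
    p_mat = _transition_matrix(g).T.tocsr()
    dangling = np.asarray(g.adjacency.sum(axis=1)).ravel() == 0
    p = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(max_iter):
        dangling_mass = p[dangling].sum() / n
        p_next = damping * (p_mat @ p + dangling_mass) + teleport
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {max_iter} iterations "
            f"(residual {np.abs(p_next - p).sum():.3e})"
        )
    raw = p / p.sum()
    values = raw
    if rescale:
        lo, hi = raw.min(), raw.max()
        if hi - lo < 1e-15:
            values = np.full(n, 0.5)
        else:
            values = (raw - lo) / (hi - lo)
    return LensValues(
        values,
        lens_name="pagerank",
        metadata={"raw": raw, "damping": damping, "rescaled": rescale},
    )


def fiedler_lens(g: AttributedGraph) -> LensValues:
    """Fiedler vector: unit-norm Laplacian eigenvector for lambda_2.

    Requires a connected graph with at least two nodes (otherwise
    ``lambda_2 = 0`` and the bipartition is meaningless).  The sign is
    fixed so the lowest-id node with a nonzero entry is positive, making
    the induced bipartition deterministic.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("Fiedler vector needs at least 2 nodes")
    n_comp, assign = _cc(g.adjacency, directed=False)
    if n_comp > 1:
        c0 = int(np.flatnonzero(assign == 0)[0])
        c1 = int(np.flatnonzero(assign == 1)[0])
        raise ValueError(
            "graph is disconnected (lambda_2 = 0): e.g. nodes "
            f"{c0} and {c1} lie in different components"
        )
    a = g.adjacency.toarray()
    lap = np.diag(a.sum(axis=1)) - a
    eigvals, eigvecs = np.linalg.eigh(lap)
    vec = eigvecs[:, 1]
    vec = vec / np.linalg.norm(vec)
    nz = np.flatnonzero(np.abs(vec) > 1e-12)
    if nz.size and vec[nz[0]] < 0:
        vec = -vec
    return LensValues(
        vec, lens_name="fiedler", metadata={"lambda2": float(eigvals[1])}
    )


def density_lens(g: AttributedGraph, scale: float) -> LensValues:
    """Graph density ``f(v) = sum_u exp(-D(u, v) / scale)``.

    ``D`` is the unweighted hop distance; the ``u = v`` term contributes
    ``exp(0) = 1`` and unreachable pairs contribute 0 (the continuous
    limit of ``exp(-inf)``).  Large values mark nodes close to many
    others.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    dist = shortest_path(g.adjacency, method="D", directed=False, unweighted=True)
    with np.errstate(over="ignore"):
        contrib = np.exp(-dist / scale)
    contrib[~np.isfinite(dist)] = 0.0
    return LensValues(
        contrib.sum(axis=1), lens_name="density", metadata={"scale": scale}
    )


def embedding_lens(
    embeddings: np.ndarray,
    reducer: Callable[[np.ndarray], np.ndarray] | None = None,
    d: int = 2,
    reducer_name: str = "identity",
    seed: int | None = None,
) -> LensValues:
    """Reduce precomputed node embeddings to a d-dimensional lens.

    The reducer is injected (identity, a fitted PCA/t-SNE/UMAP adapter,
    ...) so the lens stays agnostic of how the embeddings were produced;
    its name and seed are recorded in the lens metadata.
    """
    emb = np.asarray(embeddings, dtype=float)
    if emb.ndim == 1:
        emb = emb[:, None]
    if not np.isfinite(emb).all():
        raise ValueError("embeddings contain NaN/Inf")
    if d not in (1, 2):
        raise ValueError("lens dimension d must be 1 or 2")
    if reducer is None:
        if emb.shape[1] != d:
            raise ValueError(
                f"identity reducer requires d' == d, got {emb.shape[1]} != {d}"
            )
        reduced = emb
    else:
        reduced = np.asarray(reducer(emb), dtype=float)
        if reduced.ndim == 1:
            reduced = reduced[:, None]
    if reduced.shape[1] != d:
        raise ValueError(
            f"reducer produced {reduced.shape[1]} columns, expected {d}"
        )
    return LensValues(
        reduced,
        lens_name=f"embedding[{reducer_name}]",
        metadata={"reducer": reducer_name, "seed": seed},
    )


def supervised_prob_lens(
    class_probabilities: np.ndarray, positive_class: int = 1
) -> LensValues:
    """Positive-class probability of a binary node classifier as a lens.

    Rows must be two-column probability vectors summing to one; the
    returned lens is the positive-class column and already lives in
    ``[0, 1]``.
    """
    probs = np.asarray(class_probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("expected an N x 2 class-probability table")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1")
    if positive_class not in (0, 1):
        raise ValueError("positive_class must be 0 or 1")
    return LensValues(
        probs[:, positive_class],
        lens_name="supervised_prob",
        metadata={"positive_class": positive_class},
    )
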