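"""Core graph containers and on-disk formats.

The central object is :class:`AttributedGraph`: a simple undirected graph
with contiguous integer node ids, an optional node-feature matrix and
optional integer labels (per node, or a single per-graph class).  The
adjacency matrix is kept symmetric with a zero diagonal; self-loops only
appear downstream, where pooling adds them explicitly through the ``A + I``
term.

Supported formats: whitespace/TAB edge lists (``u v [w]``), GraphML (via
networkx), DOT export, and node-feature/label tables as CSV/TSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

logger = logging.getLogger(__name__)

__all__ = [
    "AttributedGraph",
    "GraphDataset",
    "read_graph",
    "write_graph",
    "connected_components",
]


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed as a graph."""


@dataclass
class AttributedGraph:
    """Undirected attributed graph with 0-based contiguous node ids.

    Parameters
    ----------
    adjacency
        Symmetric ``N x N`` nonnegative sparse matrix with a zero diagonal.
    features
        ``N x k`` real feature matrix (``k >= 0``).
    labels
        Optional integer class per node (length ``N``) or a single
        per-graph class.
    original_ids
        Mapping from internal id (0..N-1) to the id used in the source
        file, retained so summaries can be traced back.
    """

    adjacency: sp.csr_matrix
    features: np.ndarray | None = None
    labels: np.ndarray | int | None = None
    name: str = ""
    original_ids: dict[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency, dtype=float)
        a.eliminate_zeros()
        if a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if (abs(a - a.T)).max() > 1e-12 if a.nnz else False:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("input graphs must not carry self-loops")
        if a.nnz and a.data.min() < 0:
            raise ValueError("adjacency must be nonnegative")
        self.adjacency = a
        if self.features is None:
            self.features = np.zeros((a.shape[0], 0))
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features[:, None]
        if self.features.shape[0] != a.shape[0]:
            raise ValueError(
                f"features have {self.features.shape[0]} rows for "
                f"{a.shape[0]} nodes"
            )
        if isinstance(self.labels, (list, tuple, np.ndarray)):
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != a.shape[0]:
                raise ValueError("per-node labels must have length N")

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: Iterable[tuple[int, int]] | Iterable[tuple[int, int, float]],
        features: np.ndarray | None = None,
        labels=None,
        name: str = "",
    ) -> "AttributedGraph":
        """Build a graph from an edge iterable on nodes ``0..n_nodes-1``.

        Parallel edges collapse to one edge with summed weight; self-loops
        are dropped with a warning.
        """
        weight: dict[tuple[int, int], float] = {}
        dropped = 0
        for e in edges:
            u, v = int(e[0]), int(e[1])
            w = float(e[2]) if len(e) > 2 else 1.0
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise IndexError(f"edge ({u},{v}) outside 0..{n_nodes - 1}")
            if u == v:
                dropped += 1
                continue
            key = (min(u, v), max(u, v))
            weight[key] = weight.get(key, 0.0) + w
        if dropped:
            warnings.warn(f"dropped {dropped} self-loop(s) from input graph")
        if weight:
            rows, cols, data = [], [], []
            for (u, v), w in weight.items():
                rows += [u, v]
                cols += [v, u]
                data += [w, w]
            a = sp.csr_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes))
        else:
            a = sp.csr_matrix((n_nodes, n_nodes))
        return cls(a, features=features, labels=labels, name=name)

    # -- basic views ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of undirected edges as ``(u, v)`` with ``u < v``."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def edge_weights(self) -> dict[tuple[int, int], float]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return {
            (int(u), int(v)): float(w)
            for u, v, w in zip(coo.row, coo.col, coo.data)
        }

    def degrees(self) -> np.ndarray:
        """Unweighted degree of each node."""
        binary = self.adjacency.copy()
        binary.data = np.ones_like(binary.data)
        return np.asarray(binary.sum(axis=1)).ravel()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(range(self.n_nodes))
        for (u, v), w in self.edge_weights().items():
            g.add_edge(u, v, weight=w)
        return g

    def subgraph_components(self, node_subset: Iterable[int]) -> list[list[int]]:
        return connected_components(self, node_subset)


@dataclass
class GraphDataset:
    """Ordered collection of graphs with one class label per graph."""

    graphs: list[AttributedGraph]
    graph_labels: np.ndarray
    split_seed: int = 0

    def __post_init__(self) -> None:
        self.graph_labels = np.asarray(self.graph_labels, dtype=int)
        if len(self.graphs) != len(self.graph_labels):
            raise ValueError("one label per graph required")
        classes = np.unique(self.graph_labels)
        if classes.size and not np.array_equal(classes, np.arange(classes.size)):
            raise ValueError("class ids must be dense from 0")

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.graph_labels).size)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sort_key(x):
    try:
        return (0, int(x))
    except (TypeError, ValueError):
        return (1, str(x))


def _read_edgelist(path: Path) -> tuple[list, list[tuple]]:
    """Parse a whitespace/TSV edge list into (original node ids, edges)."""
    nodes: set = set()
    raw_edges: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'u v [w]', got {line!r}"
                )
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise GraphFormatError(
                        f"{path}:{lineno}: bad weight {parts[2]!r}"
                    ) from None
                raw_edges.append((u, v, w))
            else:
                raw_edges.append((u, v))
            nodes.update((u, v))
    return sorted(nodes, key=_sort_key), raw_edges


def _read_features(path: Path, id_map: Mapping[object, int], n: int) -> np.ndarray:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(path, sep=sep)
    if "node_id" not in table.columns:
        raise GraphFormatError(f"{path}: feature table needs a node_id column")
    if len(table) != n:
        raise ValueError(
            f"feature table has {len(table)} rows for {n} nodes"
        )
    feats = np.zeros((n, table.shape[1] - 1))
    cols = [c for c in table.columns if c != "node_id"]
    for _, row in table.iterrows():
        raw = row["node_id"]
        candidates = [raw, str(raw)]
        try:
            candidates += [int(float(raw)), str(int(float(raw)))]
        except (TypeError, ValueError):
            pass
        key = next((c for c in candidates if c in id_map), None)
        if key is None:
            raise GraphFormatError(f"{path}: unknown node id {raw!r}")
        feats[id_map[key]] = row[cols].to_numpy(dtype=float)
    return feats


def read_graph(
    path: str | Path,
    format: str = "edgelist",
    features_path: str | Path | None = None,
) -> AttributedGraph:
    """Read a graph from disk, remapping node ids to ``0..N-1``.

    The original ids are retained in ``original_ids`` so a round trip
    through the id map reproduces the source graph.  Directed GraphML
    input is symmetrized with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edgelist":
        originals, raw_edges = _read_edgelist(path)
        id_map = {o: i for i, o in enumerate(originals)}
        edges = [
            (id_map[e[0]], id_map[e[1]], *e[2:]) for e in raw_edges
        ]
        n = len(originals)
    elif format == "graphml":
        gx = nx.read_graphml(path)
        if gx.is_directed():
            warnings.warn(f"{path}: directed GraphML symmetrized")
            gx = gx.to_undirected()
        originals = sorted(gx.nodes, key=_sort_key)
        id_map = {o: i for i, o in enumerate(originals)}
        edges = [
            (id_map[u], id_map[v], float(d.get("weight", 1.0)))
            for u, v, d in gx.edges(data=True)
        ]
        n = len(originals)
    else:
        raise ValueError(f"unknown format {format!r}")
    g = AttributedGraph.from_edges(n, edges, name=path.stem)
    g.original_ids = {i: o for o, i in id_map.items()}
    if features_path is not None:
        g.features = _read_features(Path(features_path), id_map, n)
    return g


def _dot_escape(val) -> str:
    return '"%s"' % str(val).replace('"', r"\"")


def write_graph(g, path: str | Path, format: str = "graphml") -> Path:
    """Write an :class:`AttributedGraph` or a nerve summary to disk.

    Summary graphs (anything exposing ``node_attributes()`` and
    ``edge_attributes()``) carry cluster size, aggregate values and the
    semantic/structural flags as attributes in GraphML and DOT output.
    """
    path = Path(path)
    is_summary = hasattr(g, "node_attributes")
    if is_summary:
        gx = nx.Graph(name=getattr(g, "name", ""))
        for i, attrs in enumerate(g.node_attributes()):
            gx.add_node(i, **attrs)
        for e in g.edge_attributes():
            u, v = e.pop("source"), e.pop("target")
            gx.add_edge(u, v, **e)
    else:
        gx = g.to_networkx()
        for i in range(g.n_nodes):
            if g.features.shape[1]:
                for j in range(g.features.shape[1]):
                    gx.nodes[i][f"f{j + 1}"] = float(g.features[i, j])
            if isinstance(g.labels, np.ndarray):
                gx.nodes[i]["label"] = int(g.labels[i])

    if format == "graphml":
        for _, _, d in gx.edges(data=True):
            for k, v in list(d.items()):
                if isinstance(v, (bool, np.bool_)):
                    d[k] = bool(v)
        nx.write_graphml(gx, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            for u, v, d in gx.edges(data=True):
                w = d.get("weight", 1.0)
                if w == 1.0:
                    fh.write(f"{u}\t{v}\n")
                else:
                    fh.write(f"{u}\t{v}\t{w!r}\n")
            for u in gx.nodes:
                if gx.degree(u) == 0:
                    fh.write(f"{u}\t{u}\n")  # placeholder for isolated node
    elif format == "dot":
        lines = ["graph summary {"]
        for u in sorted(gx.nodes):
            attrs = ", ".join(
                f"{k}={_dot_escape(v)}" for k, v in sorted(gx.nodes[u].items())
            )
            lines.append(f"  {u} [{attrs}];" if attrs else f"  {u};")
        for u, v in sorted(tuple(sorted(e)) for e in gx.edges):
            d = gx.edges[u, v]
            attrs = ", ".join(
                f"{k}={_dot_escape(str(val).lower() if isinstance(val, (bool, np.bool_)) else val)}"
                for k, val in sorted(d.items())
            )
            lines.append(f"  {u} -- {v} [{attrs}];" if attrs else f"  {u} -- {v};")
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def connected_components(
    g: AttributedGraph, node_subset: Iterable[int] | None = None
) -> list[list[int]]:
    """Connected components of the subgraph induced by ``node_subset``.

    Blocks are returned as sorted id lists, ordered by their minimum
    member id so downstream cluster numbering is deterministic.
    """
    if node_subset is None:
        subset = np.arange(g.n_nodes)
    else:
        subset = np.asarray(sorted(set(int(v) for v in node_subset)), dtype=int)
    if subset.size == 0:
        return []
    if subset.min() < 0 or subset.max() >= g.n_nodes:
        raise IndexError("node_subset contains out-of-range ids")
    sub = g.adjacency[subset][:, subset]
    n_comp, assign = _cc(sub, directed=False)
    blocks: list[list[int]] = [[] for _ in range(n_comp)]
    for local, comp in enumerate(assign):
        blocks[comp].append(int(subset[local]))
    return sorted((sorted(b) for b in blocks), key=lambda b: b[0])
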