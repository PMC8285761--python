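"""Minimal GCN forward machinery and the embed-pool-classify architecture.

A graph convolutional layer acts on node features as

    ``X_{l+1} = act( D^{-1/2} (A + I) D^{-1/2} X_l W_l )``

with self-loop-augmented adjacency and its (weighted) degree matrix.
The classifier stacks ``L_E`` embedding layers on the input graph, pools
with a Mapper-based assignment (``A' = S^T (A + I) S``, ``X' = S^T X``),
runs ``L_C`` layers on the pooled graph, optionally pools again through
the remaining cover sizes, and finishes with a permutation-invariant
readout: feature-wise node mean, linear layer, softmax.

Training (:func:`train_demo`) is implemented natively in numpy with a
hand-written reverse pass and an Adam optimizer.  This covers the
PageRank-based pooling operator, whose assignment matrices depend only
on graph structure and are therefore fixed during optimization; all
per-graph propagation and assignment matrices are precomputed once.
Training through the kernel-based (DMP) assignment would require
differentiating the lens itself and is not part of this trainer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .graph_io import AttributedGraph, GraphDataset
from .pooling import SoftAssignment, mpr_assignment

__all__ = [
    "GCNLayerParams",
    "ClassifierParams",
    "TrainConfig",
    "normalized_adjacency",
    "gcn_forward",
    "readout_classify",
    "classify_graph",
    "train_demo",
]


@dataclass
class GCNLayerParams:
    """Weight matrix and activation of one graph convolutional layer."""

    weight: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if self.weight.ndim != 2:
            raise ValueError("layer weight must be 2-dimensional")
        if not np.isfinite(self.weight).all():
            raise ValueError("layer weight contains non-finite entries")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class ClassifierParams:
    """All weights of the embed-pool-classify architecture."""

    embed_layers: list[GCNLayerParams]
    classify_layers: list[GCNLayerParams]
    readout_weight: np.ndarray
    readout_bias: np.ndarray

    def __post_init__(self) -> None:
        self.readout_weight = np.asarray(self.readout_weight, dtype=float)
        self.readout_bias = np.asarray(self.readout_bias, dtype=float).ravel()
        if self.readout_weight.shape[1] != self.readout_bias.shape[0]:
            raise ValueError("readout weight/bias shapes do not chain")
        if self.readout_bias.shape[0] < 2:
            raise ValueError("need at least 2 output classes")
        dims = [l.weight.shape for l in self.embed_layers + self.classify_layers]
        for (_, out_d), (in_d, _) in zip(dims, dims[1:]):
            if out_d != in_d:
                raise ValueError("consecutive layer dimensions do not chain")

    @property
    def n_classes(self) -> int:
        return self.readout_bias.shape[0]

    # -- serialization (flat JSON; all weights as nested lists) --------

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "embed": [
                {"weight": l.weight.tolist(), "activation": l.activation}
                for l in self.embed_layers
            ],
            "classify": [
                {"weight": l.weight.tolist(), "activation": l.activation}
                for l in self.classify_layers
            ],
            "readout_weight": self.readout_weight.tolist(),
            "readout_bias": self.readout_bias.tolist(),
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            embed_layers=[
                GCNLayerParams(np.array(l["weight"]), l["activation"])
                for l in payload["embed"]
            ],
            classify_layers=[
                GCNLayerParams(np.array(l["weight"]), l["activation"])
                for l in payload["classify"]
            ],
            readout_weight=np.array(payload["readout_weight"]),
            readout_bias=np.array(payload["readout_bias"]),
        )

    @classmethod
    def glorot_init(
        cls,
        in_dim: int,
        hidden_dims: tuple[int, ...],
        classify_dims: tuple[int, ...],
        n_classes: int,
        seed: int = 0,
    ) -> "ClassifierParams":
        """Uniform Glorot initialization with a pinned seed."""
        rng = np.random.default_rng(seed)

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        embed, d = [], in_dim
        for h in hidden_dims:
            embed.append(GCNLayerParams(glorot(d, h), "relu"))
            d = h
        classify = []
        for i, h in enumerate(classify_dims):
            act = "identity" if i == len(classify_dims) - 1 else "relu"
            classify.append(GCNLayerParams(glorot(d, h), act))
            d = h
        return cls(
            embed_layers=embed,
            classify_layers=classify,
            readout_weight=glorot(d, n_classes),
            readout_bias=np.zeros(n_classes),
        )


def normalized_adjacency(adjacency) -> np.ndarray:
    """Symmetric propagation matrix ``D^{-1/2} (A + I) D^{-1/2}``.

    Accepts a sparse or dense (possibly weighted) adjacency; the identity
    term guarantees every degree is at least one.
    """
    a = adjacency.toarray() if sp.issparse(adjacency) else np.asarray(adjacency, float)
    a_hat = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    return np.maximum(z, 0.0) if activation == "relu" else z


def gcn_forward(
    X: np.ndarray, adjacency, params: GCNLayerParams
) -> np.ndarray:
    """One graph convolution ``act(D^{-1/2} (A + I) D^{-1/2} X W)``."""
    m = normalized_adjacency(adjacency)
    out = _activate(m @ np.asarray(X, float) @ params.weight, params.activation)
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite output from GCN layer")
    return out


def readout_classify(
    X: np.ndarray, readout_weight: np.ndarray, readout_bias: np.ndarray
) -> np.ndarray:
    """Mean-readout classifier: ``softmax(mean_v(X) W_f + b_f)``.

    Node-permutation invariant; probabilities sum to one.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot classify an empty graph")
    logits = X.mean(axis=0) @ readout_weight + readout_bias
    logits -= logits.max()
    expl = np.exp(logits)
    return expl / expl.sum()


@dataclass
class _PreparedGraph:
    """Fixed (weight-independent) matrices of one graph's forward pass."""

    features: np.ndarray
    prop: list[np.ndarray]         # propagation matrix per conv stage
    assign: list[np.ndarray]       # pooling assignment per level


def _prepare(
    g: AttributedGraph,
    cover_sizes: tuple[int, ...],
    overlap: float,
    assignments: list[SoftAssignment] | None = None,
) -> _PreparedGraph:
    """Precompute propagation and assignment matrices for one graph.

    Stage 0 propagates on the input graph; after the first pooling level
    stage 1 propagates on the pooled graph (``A' + I`` renormalized);
    later levels only pool features before the readout.
    """
    prop = [normalized_adjacency(g.adjacency)]
    assign: list[np.ndarray] = []
    current = g
    a_hat = g.adjacency + sp.identity(g.n_nodes, format="csr")
    for level, size in enumerate(cover_sizes):
        if assignments is not None:
            S = assignments[level]
        else:
            S = mpr_assignment(current, size, overlap_g=overlap)
        s = S.matrix
        pooled_a = np.asarray(s.T @ (a_hat @ s))
        assign.append(s)
        if level == 0:
            prop.append(normalized_adjacency(pooled_a))
        off = pooled_a.copy()
        np.fill_diagonal(off, 0.0)
        current = AttributedGraph(sp.csr_matrix(off))
        a_hat = sp.csr_matrix(pooled_a)
    return _PreparedGraph(features=g.features, prop=prop, assign=assign)


def _forward(prep: _PreparedGraph, params: ClassifierParams, cache: bool = False):
    """Forward pass; optionally keep intermediates for the reverse pass."""
    x = prep.features
    trace = []
    for layer in params.embed_layers:
        pre = prep.prop[0] @ x @ layer.weight
        post = _activate(pre, layer.activation)
        trace.append(("conv", prep.prop[0], x, pre, layer))
        x = post
    if prep.assign:
        trace.append(("pool", prep.assign[0]))
        x = prep.assign[0].T @ x
        for layer in params.classify_layers:
            pre = prep.prop[1] @ x @ layer.weight
            post = _activate(pre, layer.activation)
            trace.append(("conv", prep.prop[1], x, pre, layer))
            x = post
        for s in prep.assign[1:]:
            trace.append(("pool", s))
            x = s.T @ x
    else:
        for layer in params.classify_layers:
            pre = prep.prop[0] @ x @ layer.weight
            post = _activate(pre, layer.activation)
            trace.append(("conv", prep.prop[0], x, pre, layer))
            x = post
    logits = x.mean(axis=0) @ params.readout_weight + params.readout_bias
    logits = logits - logits.max()
    expl = np.exp(logits)
    probs = expl / expl.sum()
    if cache:
        return probs, x, trace
    return probs


def classify_graph(
    g: AttributedGraph,
    params: ClassifierParams,
    cover_sizes: tuple[int, ...] = (4, 1),
    overlap: float = 0.25,
    assignments: list[SoftAssignment] | None = None,
) -> np.ndarray:
    """Class probabilities for one graph through embed-pool-classify-readout.

    Pooling uses the PageRank interval-cover assignment by default;
    precomputed assignments (e.g. DMP matrices, or an identity matrix for
    a pooling-free ablation) can be injected via ``assignments``.
    Deterministic given parameters, and invariant to node relabeling.
    """
    prep = _prepare(g, cover_sizes, overlap, assignments=assignments)
    return _forward(prep, params)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Hyperparameters of the classification demo.

    Defaults are desk-scale: two 16-unit embedding layers, one 16-unit
    classification layer, PageRank pooling through cover sizes (4, 1)
    with 25% interval overlap, Adam at ``lr = 0.01``, at most 30 epochs
    with early stopping on a 20% validation split.
    """

    hidden_dims: tuple[int, ...] = (16, 16)
    classify_dims: tuple[int, ...] = (16,)
    cover_sizes: tuple[int, ...] = (4, 1)
    overlap: float = 0.25
    lr: float = 0.01
    max_epochs: int = 30
    batch_size: int = 32
    val_fraction: float = 0.2
    patience: int = 10
    seed: int = 0


class _Adam:
    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, gr) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * gr
            self.v[i] = b2 * self.v[i] + (1 - b2) * gr * gr
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + eps)


def _flatten_params(params: ClassifierParams) -> list[np.ndarray]:
    return (
        [l.weight for l in params.embed_layers]
        + [l.weight for l in params.classify_layers]
        + [params.readout_weight, params.readout_bias]
    )


def _backward(
    prep: _PreparedGraph, params: ClassifierParams, label: int
) -> tuple[float, list[np.ndarray]]:
    """Cross-entropy loss and gradients for one graph (reverse pass)."""
    probs, x_final, trace = _forward(prep, params, cache=True)
    loss = -float(np.log(max(probs[label], 1e-300)))
    d_logits = probs.copy()
    d_logits[label] -= 1.0
    h = x_final.mean(axis=0)
    g_wf = np.outer(h, d_logits)
    g_bf = d_logits.copy()
    d_x = np.tile(
        (d_logits @ params.readout_weight.T) / x_final.shape[0],
        (x_final.shape[0], 1),
    )
    layer_grads: dict[int, np.ndarray] = {}
    for item in reversed(trace):
        if item[0] == "pool":
            d_x = item[1] @ d_x  # X' = S^T X  =>  dX = S dX'
        else:
            _, m, x_in, pre, layer = item
            d_pre = d_x if layer.activation == "identity" else d_x * (pre > 0)
            mx = m @ x_in
            g_w = mx.T @ d_pre
            key = id(layer.weight)
            layer_grads[key] = layer_grads.get(key, 0.0) + g_w
            d_x = m @ d_pre @ layer.weight.T  # m is symmetric
    grads = [
        layer_grads.get(id(l.weight), np.zeros_like(l.weight))
        for l in params.embed_layers + params.classify_layers
    ]
    grads += [g_wf, g_bf]
    return loss, grads


def _accuracy(preps, labels, params) -> float:
    correct = sum(
        int(np.argmax(_forward(p, params)) == y) for p, y in zip(preps, labels)
    )
    return correct / len(labels) if labels.size else float("nan")


def train_demo(
    dataset: GraphDataset, config: TrainConfig | None = None
) -> tuple[ClassifierParams, dict]:
    """Train the embed-pool-classify model on a graph dataset.

    Uses Adam with early stopping on a held-out validation split, capped
    at ``config.max_epochs`` (30 by default).  The PageRank pooling
    assignments are structural and fixed, so they are precomputed per
    graph; only the convolution and readout weights receive gradients.
    Returns the best parameters (by validation accuracy) and a history
    dict with per-epoch train/validation accuracy and loss.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]

    preps = [
        _prepare(g, config.cover_sizes, config.overlap) for g in dataset.graphs
    ]
    labels = dataset.graph_labels
    in_dim = dataset.graphs[0].features.shape[1]
    if in_dim == 0:
        raise ValueError("training requires node features")
    params = ClassifierParams.glorot_init(
        in_dim,
        config.hidden_dims,
        config.classify_dims,
        dataset.n_classes,
        seed=config.seed,
    )
    flat = _flatten_params(params)
    opt = _Adam([p.shape for p in flat], lr=config.lr)

    history = {"train_acc": [], "val_acc": [], "train_loss": []}
    best = (-1.0, None)
    stale = 0
    for epoch in range(config.max_epochs):
        rng.shuffle(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(train_idx), config.batch_size):
            batch = train_idx[start : start + config.batch_size]
            grads = [np.zeros_like(p) for p in flat]
            for i in batch:
                loss, g_list = _backward(preps[i], params, int(labels[i]))
                epoch_loss += loss
                for acc, gr in zip(grads, g_list):
                    acc += gr
            grads = [gr / len(batch) for gr in grads]
            opt.step(flat, grads)
        train_acc = _accuracy([preps[i] for i in train_idx], labels[train_idx], params)
        val_acc = _accuracy([preps[i] for i in val_idx], labels[val_idx], params)
        history["train_acc"].append(train_acc)
        history["val_acc"].append(val_acc)
        history["train_loss"].append(epoch_loss / max(len(train_idx), 1))
        if val_acc > best[0]:
            best = (val_acc, [p.copy() for p in flat])
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best[1] is not None:
        for p, b in zip(flat, best[1]):
            p[...] = b
    history["train_idx"] = train_idx.tolist()
    history["val_idx"] = val_idx.tolist()
    return params, history
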