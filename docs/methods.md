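# Methods

## The summarization model

`graphmapper` summarizes an attributed undirected graph `G = (V, E)` with
node features `X ∈ R^{N×k}` as the nerve of a cover of the graph, in four
steps:

1. **Lens.** A function `f : V → R^d` (`d ∈ {1, 2}`) assigns each node a
   low-dimensional coordinate. The lens decides *what the summary is
   about*: PageRank emphasizes random-walk importance, the Fiedler vector
   emphasizes the dominant spectral cut, a graph-density function
   emphasizes centrality, classifier probabilities or reduced embeddings
   emphasize learned semantics.
2. **Cover.** The lens codomain is covered by overlapping sets: `n`
   equal-length closed intervals with fractional overlap `g` on the line,
   or their product grid in the plane. Pulling the cover back through the
   lens yields one node set per cover element, `f^{-1}(U_i)`.
3. **Refinement.** Each pull back set is split into clusters — the
   connected components of its induced subgraph (the natural clustering
   when the space *is* a graph), or kept whole ("trivial" clustering,
   the regime in which pooling operators live). Each cluster is then
   extended with every graph edge incident to its nodes, so the cluster
   collection covers the *whole* graph, not just its vertex set.
4. **Nerve.** One summary node per cluster; two summary nodes are joined
   when their clusters intersect. Because clusters carry nodes and
   incident edges, an intersection can consist of shared nodes (a
   **semantic** edge: the lens maps the clusters to overlapping regions)
   or shared edges (a **structural** edge: the clusters are wired
   together in `G`). Without the edge-extension step only semantic edges
   exist; the structural variant's edge set therefore always contains
   the plain variant's, and the difference is exactly the connectivity
   information the node-only construction discards.

Assumptions: graphs are simple and undirected with nonnegative weights;
self-loops are never stored on inputs (pooling re-adds them explicitly);
node ids are contiguous from 0 with original ids kept as metadata.

## Pooling as a special case

A soft cluster assignment is a row-stochastic matrix `S ∈ R^{N×K}`; the
pooled graph is `A' = S^T (A + I) S` with features `X' = S^T X`. The
identity term makes two clusters adjacent whenever they share a node,
even without a shared edge. Realizing each column as a cover element
(the nodes with positive membership), taking trivial clustering, edge
refinement and the nerve gives a summary whose edge set equals the
off-diagonal nonzero pattern of `A'` — checked exactly, instance by
instance, in the test suite (random instances plus an exhaustive sweep
over all labeled 4-node graphs and hard 2-partitions). Columns with no
positive entries have empty cover elements and hence no nerve vertex;
they are correspondingly zero in `A'`.

Two assignment constructions are built in:

* **MPR (PageRank + intervals).** The lens is PageRank with damping
  0.85, computed by power iteration with uniform teleport and the
  standard dangling-node fix, min-max rescaled so the cover of `[0, 1]`
  is fully used. Each node's row spreads uniformly over the cover
  elements containing its lens value (one-hot except on overlaps, the
  overlap fraction defaulting to 0.25). Cover elements with empty pull
  backs are dropped (column map recorded), so the effective `K` can be
  smaller than requested. The assignment depends only on graph
  structure, never on model weights.
* **DMP (RBF kernels).** The cover is `n` Gaussian kernels
  `φ(x, c) = exp(-(x - c)² / δ)` centered at equally spaced points of
  `[0, 1]` (a single kernel sits at 0.5); the assignment row is the
  normalized vector of kernel responses to the sigmoid-squashed lens
  value. The scale defaults to `δ = 1/n²`. Rows are low-entropy by
  geometry — a point on a line is close to few centers — and the mean
  row entropy is monotone in `δ` (tested). The construction is smooth in
  the lens, which is what makes it trainable in principle; this package
  ships the exact deterministic forward pass, and its hierarchical
  variant feeds the recomputed PageRank coordinate of each level into
  the kernels.

Hierarchical pooling applies assignment + pooling through a decreasing
cover-size schedule (e.g. 20 → 5). Between levels the pooled adjacency's
diagonal is set aside as self-loop weight and the PageRank lens is
recomputed on the weighted off-diagonal pattern; levels that would not
shrink the graph are skipped with a warning.

## Classification architecture

Graph convolutions follow the symmetric-normalized rule
`X_{l+1} = σ(D̂^{-1/2} Â D̂^{-1/2} X_l W_l)` with `Â = A + I` and weighted
degrees; pooled adjacencies feed this rule directly without
re-binarization, preserving the shared-edge semantics above. The
classifier runs `L_E` embedding convolutions on the input graph, pools,
runs `L_C` convolutions on the (first) pooled graph, pools through any
remaining schedule levels, then applies a mean readout and a linear
softmax layer — permutation-invariant end to end (tested against node
relabelings to 1e-10).

**Training** is implemented natively in numpy: a hand-written reverse
pass through the convolution/pooling/readout chain and an Adam optimizer
(β = 0.9/0.999, ε = 1e-8). This is exact for the PageRank pooling path
because its assignment matrices are weight-independent: all propagation
and assignment matrices are precomputed once per graph, and only
convolution and readout weights receive gradients (verified against
central finite differences). Training through the kernel assignment —
where gradients must flow into the lens itself — is out of scope for
this trainer. Demo defaults: two 16-unit embedding layers, one 16-unit
classification layer, cover sizes (4, 1) at 25% overlap, learning rate
0.01, batch size 32, at most 30 epochs with early stopping (patience 10)
on a 20% validation split, uniform Glorot initialization under a pinned
seed. These sizes are deliberately small so the demo trains in seconds
on one CPU.

## Synthetic data

The fixture generators emulate the structures the method is designed to
expose, with exact ground truth:

* **Spammer network** (default 20 spammers, 180 normal users in 15
  communities; `p_spam = 0.3`, `p_comm = 0.2`): spammers attach to any
  node, normal users only within their community, so spammers form a
  high-degree hub and communities form near-disconnected satellites.
* **Standard substrates**: rings, paths, stars, barbells (two cliques
  plus one bridge), two-block SBMs, Erdos-Renyi graphs.
* **Classification dataset**: balanced rings (class 0) vs two-block SBMs
  (`p_in = 0.8`, `p_out = 0.1`, class 1) with matched sizes 10–20 and
  constant + degree features.

What these do *not* emulate: heavy-tailed degree distributions of real
social graphs, node attributes correlated with community identity beyond
degree, edge weights, and label noise. Passing tests therefore establish
the correctness of the constructions (covers, nerves, pooled adjacency,
gradients) and the learnability of a clean structural signal — not
benchmark-level classification performance on real molecular or social
datasets, which additionally depends on lens capacity and tuning.

## Numerical choices

* Cover elements are **closed** sets, so boundary lens values join both
  neighbors (measure-zero deviation from open covers; avoids dropping
  nodes). Interval membership uses a 1e-12 endpoint tolerance.
* Interval construction: length `ℓ = R / (1 + (n-1)(1-g))`, step
  `ℓ(1-g)`; overlap is measured relative to element length, and the last
  endpoint is pinned to the range maximum against rounding drift.
* Lens values are affinely rescaled onto a bounded cover's range before
  membership (guaranteeing total coverage); a constant lens dimension
  maps to the range midpoint. Covers with unbounded endpoints (the
  half-line pair used for spectral bipartitions) are taken at face
  value.
* PageRank: L1 convergence below `tol = 1e-10`, at most 1000 iterations
  (error on non-convergence), raw vector renormalized to sum exactly 1.
* Fiedler vector: dense symmetric eigendecomposition; unit norm; sign
  fixed so the lowest-id node with a nonzero entry is positive;
  disconnected graphs are rejected with the offending components named.
  Under eigenvalue multiplicity (vertex-transitive graphs) the returned
  vector is whichever the deterministic solver produces, still unit-norm
  and orthogonal to the constant vector.
* Unreachable pairs contribute 0 to the density lens (continuous limit
  of `exp(-∞)`).
* DMP kernel rows are floored at 1e-300 before normalization when every
  kernel underflows (warning logged).
* Cluster ordering is `(cover element, minimum node id)` and component
  blocks are ordered by minimum member, so summaries are bit-identical
  across runs. Cluster aggregates: size, mean lens, feature mean, and
  majority node label with ties broken toward the smaller class id.
* Summary graphs never contain self-edges, and clusters with identical
  node sets from different cover elements remain distinct vertices.

## Known limitations

* No gradient training through the kernel (DMP) assignment; DMP is
  forward-only here.
* Lenses of dimension above 2, adaptive (equal-mass) covers, statistical
  clustering beyond connected components, and directed or multigraph
  semantics are unsupported.
* The dense Fiedler and density lenses are intended for graphs up to a
  few thousand nodes; PageRank and the Mapper pipeline itself scale
  linearly and go much further.
* Edge lists cannot represent isolated nodes losslessly; use GraphML for
  graphs that have them.
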