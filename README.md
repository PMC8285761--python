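# graphmapper

Topologically grounded summarization and pooling for attributed graphs —
molecular, biological and social networks alike.

Large attributed graphs are hard to see and expensive to classify. This
package condenses them with the Mapper construction from topological
data analysis, adapted so that the *edges* of the graph are part of the
cover being summarized: a lens function `f : V → R^d` spreads the nodes
over the line or plane, an overlapping cover of the lens codomain pulls
back to overlapping node sets, each set splits into clusters (connected
components of its induced subgraph), every cluster is extended with its
incident edges, and the summary is the nerve — one node per cluster,
with an edge whenever two clusters share a node (**semantic**: lens
similarity) or share an edge (**structural**: graph connectivity).
Skipping the edge-extension step recovers the node-only construction,
whose summaries carry semantic edges only and provably lose
connectivity information; the package ships both so they can be
compared on the same lens and cover.

The same construction yields pooling operators for graph neural
networks. A row-stochastic assignment `S ∈ R^{N×K}` pools a graph as

    A' = Sᵀ (A + I) S,    X' = Sᵀ X,

and the off-diagonal nonzero pattern of `A'` equals the nerve of the
cover whose elements are the supports of the columns of `S` — soft
cluster assignment pooling *is* a Mapper summary. Two assignments are
built in: **MPR** (fixed PageRank lens with an overlapping interval
cover; rows uniform over covering elements) and **DMP** (RBF-kernel
cover `φ(x, c) = exp(-(x-c)²/δ)` with normalized kernel responses,
smooth in the lens, default scale `δ = 1/n²`). A small GCN
(`X_{l+1} = σ(D̂^{-1/2}ÂD̂^{-1/2} X_l W_l)`, `Â = A + I`) with mean
readout plugs these into an embed–pool–classify architecture, including
a pure-numpy trainer (Adam, hand-written reverse pass) for the
fixed-assignment path.

## Worked example

Summarize a synthetic spammer network — 20 spammers wired to everyone,
180 normal users in 15 small communities — with a PageRank lens and ten
10%-overlap intervals:

```python
import numpy as np
from graphmapper import (fixtures, pagerank_lens, make_interval_cover,
                         structural_mapper, plain_mapper, render_summary)

g = fixtures.spammer_graph(seed=0)                 # 200 nodes, 1339 edges
lens = pagerank_lens(g)                            # damping 0.85, rescaled to [0,1]
cover = make_interval_cover(10, 0.1, 0.0, 1.0)
summary = structural_mapper(g, lens, cover)
plain = plain_mapper(g, lens, cover)               # node-cover variant

print(summary.n_nodes, summary.n_edges, len(summary.semantic_edges()))
print(plain.n_nodes, plain.n_edges)
top = max(range(summary.n_nodes),
          key=lambda i: summary.aggregates[i]["mean_lens"])
print(summary.aggregates[top]["majority_label"],
      sum(1 for e in summary.edges if top in (e["source"], e["target"])))
render_summary(summary, path="spammer.dot")        # graphviz-ready
```

This prints:

```
80 398 13
80 13
1 64
```

Both variants find the same 80 clusters, but the node-only summary
keeps just 13 edges (clusters overlapping in lens value), while the
structural summary restores 398 connections. The cluster with the
highest mean PageRank is pure spam (majority label 1) and touches 64
summary edges — the hub through which the spammers reach the satellite
communities, invisible in the semantic-only summary.

The same pipeline is available from the shell:

```sh
graphmapper gen-fixture --kind spammer --seed 0 --out-prefix spam
graphmapper summarize --graph spam.edgelist --lens pagerank \
    --n 10 --overlap 0.1 --dot spam.dot
graphmapper pool --graph spam.edgelist --method mpr \
    --cover-sizes 8,2 --out-prefix pooled
graphmapper demo-classify --n-graphs 100 --seed 0
```

See `docs/methods.md` for the model, parameter meanings, numerical
conventions and limitations.

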