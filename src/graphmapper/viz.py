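"""Visualization export: colored DOT files and hierarchical (n, g) grids.

The tested artifact is plain DOT text — pure and byte-deterministic for
a given summary and spec.  Node width scales with the square root of the
cluster size; fill color comes from a matplotlib-style colormap over the
chosen aggregate (normalized per figure by min-max over the clusters,
recorded in the DOT comment header).  Semantic-only edges are dashed,
edges with a structural component solid.  Rasterization is delegated to
an external layout engine (e.g. ``dot -Tpng``) and never required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .graph_io import AttributedGraph
from .lenses import LensValues
from .mapper import SummaryGraph, structural_mapper

__all__ = ["VizSpec", "render_summary", "hierarchical_grid"]

# small built-in colormaps (anchor colors, linearly interpolated) so DOT
# export stays dependency-free and byte-stable
_COLORMAPS = {
    "viridis": [(68, 1, 84), (59, 82, 139), (33, 145, 140), (94, 201, 98), (253, 231, 37)],
    "coolwarm": [(59, 76, 192), (222, 220, 218), (180, 4, 38)],
    "greys": [(245, 245, 245), (40, 40, 40)],
}


@dataclass
class VizSpec:
    """What to draw: the aggregate for color, the size rule, the colormap."""

    color_by: str = "mean_lens"
    size_by: str = "cluster_size"
    colormap: str = "viridis"
    label_nodes: bool = True

    def __post_init__(self) -> None:
        if self.color_by not in ("mean_lens", "majority_label", "feature_mean"):
            raise ValueError(f"unknown color_by {self.color_by!r}")
        if self.size_by not in ("cluster_size", "constant"):
            raise ValueError(f"unknown size_by {self.size_by!r}")
        if self.colormap not in _COLORMAPS:
            raise ValueError(
                f"unknown colormap {self.colormap!r}; choose from {sorted(_COLORMAPS)}"
            )


def _interp_color(anchors, t: float) -> str:
    t = min(max(t, 0.0), 1.0)
    pos = t * (len(anchors) - 1)
    i = min(int(pos), len(anchors) - 2)
    frac = pos - i
    rgb = [
        round(a + (b - a) * frac) for a, b in zip(anchors[i], anchors[i + 1])
    ]
    return "#%02x%02x%02x" % tuple(rgb)


def _color_values(s: SummaryGraph, spec: VizSpec) -> list[float]:
    vals = []
    for agg in s.aggregates:
        v = agg.get(spec.color_by)
        if v is None:
            raise ValueError(
                f"summary has no {spec.color_by!r} aggregate to color by"
            )
        if isinstance(v, tuple):
            v = v[0]
        vals.append(float(v))
    return vals


def render_summary(
    s: SummaryGraph, spec: VizSpec | None = None, path: str | Path | None = None
) -> str:
    """Render a summary graph to DOT text (optionally writing it out).

    Pure: identical summary and spec give byte-identical output.  Every
    summary edge appears exactly once, dashed when it is semantic-only
    and solid when it has a structural component, with both flags
    attached as attributes.
    """
    spec = spec or VizSpec()
    colors = _color_values(s, spec)
    lo, hi = (min(colors), max(colors)) if colors else (0.0, 1.0)
    span = hi - lo
    anchors = _COLORMAPS[spec.colormap]
    lines = [
        "graph summary {",
        f"  // color_by={spec.color_by} normalized min={lo:.6g} max={hi:.6g} cmap={spec.colormap}",
        "  node [style=filled, shape=circle, fixedsize=true];",
    ]
    for i, (cluster, value) in enumerate(zip(s.clusters, colors)):
        t = (value - lo) / span if span > 0 else 0.5
        if spec.size_by == "cluster_size":
            width = 0.3 + 0.25 * math.sqrt(len(cluster.nodes))
        else:
            width = 0.6
        label = str(len(cluster.nodes)) if spec.label_nodes else ""
        lines.append(
            f'  {i} [width={width:.3f}, fillcolor="{_interp_color(anchors, t)}", '
            f'label="{label}", tooltip="{spec.color_by}={value:.4g}"];'
        )
    for e in s.edges:
        style = "solid" if e["structural"] else "dashed"
        lines.append(
            f"  {e['source']} -- {e['target']} [style={style}, "
            f"semantic={str(bool(e['semantic'])).lower()}, "
            f"structural={str(bool(e['structural'])).lower()}];"
        )
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def hierarchical_grid(
    g: AttributedGraph,
    lens: LensValues,
    n_list=(16, 64, 256),
    g_list=(0.1, 0.25, 0.35),
    clustering: str = "connected_components",
    out_dir: str | Path | None = None,
    spec: VizSpec | None = None,
) -> dict[tuple[int, float], SummaryGraph]:
    """One summary per (cover size, overlap) pair — a multi-resolution view.

    More cover elements give more granular summaries; more overlap gives
    more connectivity, so features persisting across the grid are robust
    structure rather than resolution artifacts.  Files (when ``out_dir``
    is given) are named ``summary_n{n}_g{g}.dot``, plus an ``index.tsv``
    listing each cell's node and edge counts.
    """
    from .covers import make_grid_cover, make_interval_cover

    if not n_list or not g_list:
        raise ValueError("n_list and g_list must be nonempty")
    out: dict[tuple[int, float], SummaryGraph] = {}
    index_rows = []
    for overlap in g_list:
        for n in n_list:
            if lens.dim == 1:
                cover = make_interval_cover(int(n), float(overlap), 0.0, 1.0)
            else:
                side = max(1, int(round(math.sqrt(n))))
                cover = make_grid_cover(
                    side, side, float(overlap), ((0.0, 1.0), (0.0, 1.0))
                )
            summary = structural_mapper(
                g, lens, cover, clustering=clustering,
                name=f"{g.name}:n{n}:g{overlap}",
            )
            out[(int(n), float(overlap))] = summary
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                fname = out_dir / f"summary_n{n}_g{overlap}.dot"
                render_summary(summary, spec, fname)
                index_rows.append(
                    f"{n}\t{overlap}\t{summary.n_nodes}\t{summary.n_edges}\t{fname.name}"
                )
    if out_dir is not None:
        (Path(out_dir) / "index.tsv").write_text(
            "n\toverlap\tclusters\tedges\tfile\n" + "\n".join(index_rows) + "\n"
        )
    return out
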