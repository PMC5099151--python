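"""Visual-encoding export of emotion networks.

The encoding mirrors the original study's network figures: node size is
proportional to the weighted indegree (how much of the emotion the character
receives), node color darkness to the weighted outdegree (how much it
expresses), edge thickness to the edge weight, and the arrow carries the
direction.  Encodings are exported as numeric attributes in [0, 1]
(min–max scaled; all-equal degenerate case -> 0.5) so any standard graph
viewer can render them; no layout or color map is baked in.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .io_matrices import ValidationError
from .networks import EmotionNetwork, degree_indices

__all__ = ["styled_graph", "export_styled", "plot_network"]

STYLED_FORMATS = ("graphml", "gexf", "dot")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.full(len(values), 0.5)
    return (values - lo) / (hi - lo)


def styled_graph(net: EmotionNetwork) -> nx.DiGraph:
    """DiGraph with ``size``, ``darkness`` and ``thickness`` attributes in [0, 1]."""
    g = net.to_networkx()
    table = degree_indices(net)
    size = _minmax(table["weighted_indegree"].to_numpy())
    dark = _minmax(table["weighted_outdegree"].to_numpy())
    for i, name in enumerate(net.roster.names):
        g.nodes[name]["size"] = float(size[i])
        g.nodes[name]["darkness"] = float(dark[i])
        g.nodes[name]["weighted_indegree"] = float(table.loc[name, "weighted_indegree"])
        g.nodes[name]["weighted_outdegree"] = float(table.loc[name, "weighted_outdegree"])
    if net.edges:
        weights = np.array([w for _, w in sorted(net.edges.items())])
        thick = _minmax(weights)
        for k, (s, t) in enumerate(sorted(net.edges)):
            g.edges[s, t]["thickness"] = float(thick[k])
    return g


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    lines = [f'digraph "{_dot_escape(str(g.graph.get("emotion", "emotion")))}" {{']
    for k, v in sorted(g.graph.items()):
        lines.append(f'  graph ["{_dot_escape(str(k))}"="{_dot_escape(str(v))}"];')
    for n, d in g.nodes(data=True):
        attrs = ", ".join(f'{k}="{_dot_escape(str(v))}"' for k, v in sorted(d.items()))
        lines.append(f'  "{_dot_escape(str(n))}" [{attrs}];')
    for s, t, d in g.edges(data=True):
        attrs = ", ".join(f'{k}="{_dot_escape(str(v))}"' for k, v in sorted(d.items()))
        lines.append(f'  "{_dot_escape(str(s))}" -> "{_dot_escape(str(t))}" [{attrs}];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_styled(
    net: EmotionNetwork,
    path: str | Path,
    fmt: str | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a network with the visual-encoding attributes attached."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in STYLED_FORMATS:
        raise ValidationError(
            f"unknown styled format {fmt!r}; choose from {STYLED_FORMATS}"
        )
    g = styled_graph(net)
    if metadata:
        g.graph.update({str(k): v for k, v in metadata.items()})
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        g.graph["name"] = net.emotion
        nx.write_gexf(g, path)
    else:
        _write_dot(g, path)


def plot_network(net: EmotionNetwork, path: str | Path, seed: int = 0) -> None:
    """Optional static rendering with a seeded force-directed layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = styled_graph(net)
    pos = nx.spring_layout(g, seed=seed)
    sizes = [300 + 1700 * g.nodes[n]["size"] for n in g.nodes]
    darkness = [g.nodes[n]["darkness"] for n in g.nodes]
    widths = [0.5 + 3.0 * g.edges[e].get("thickness", 0.5) for e in g.edges]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        g,
        pos=pos,
        ax=ax,
        node_size=sizes,
        node_color=darkness,
        cmap="Greys",
        vmin=-0.2,  # keep the lightest node visible against white
        vmax=1.0,
        width=widths,
        edge_color="gray",
        font_size=7,
        arrows=True,
    )
    ax.set_title(net.emotion)
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
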