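"""Lineage-tree rendering via the DOT graph description language.

Trees are translated to DOT digraph text; rasterisation is delegated to
an external renderer (e.g. Graphviz ``dot``) when available — the
contract of this module ends at the DOT text.  Filled nodes represent
sampled sequences, unfilled nodes hypothetical ones; multi-population
nodes get a multi-color (wedged) fill; edge labels show the mutation
count on the edge.  Output is deterministic for fixed input and style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tree import LineageTree

__all__ = ["DotStyle", "tree_to_dot", "DEFAULT_PALETTE"]

#: deterministic default color cycle for population labels
DEFAULT_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


@dataclass(frozen=True)
class DotStyle:
    palette: dict[str, str] = field(default_factory=dict)
    font_size: float = 14.0
    line_width: float = 1.0
    show_distances: bool = True


def _quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def tree_to_dot(tree: LineageTree, style: DotStyle | None = None) -> str:
    """Translate one tree into a DOT digraph (one DOT node per tree node,
    one DOT edge per tree edge)."""
    style = style or DotStyle()
    labels = sorted(tree.population_universe())
    palette = dict(style.palette)
    for i, lab in enumerate(labels):
        palette.setdefault(lab, DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)])

    lines = [f"digraph {_quote(tree.clone_id)} {{"]
    lines.append(
        f"  node [shape=circle, fontsize={_fmt(style.font_size)}, "
        f"penwidth={_fmt(style.line_width)}];"
    )
    lines.append(
        f"  edge [fontsize={_fmt(style.font_size)}, "
        f"penwidth={_fmt(style.line_width)}];"
    )
    for node in tree.preorder():
        attrs = []
        node_labels = sorted(node.populations)
        if node.hypothetical or not node_labels:
            if not node.hypothetical and not node_labels:
                attrs.append('style=filled, fillcolor="#d9d9d9"')
        elif len(node_labels) == 1:
            attrs.append(f'style=filled, fillcolor="{palette[node_labels[0]]}"')
        else:
            colors = ":".join(palette[lab] for lab in node_labels)
            attrs.append(f'style=wedged, fillcolor="{colors}"')
        attr_text = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f"  {_quote(node.name)}{attr_text};")
    for parent, child in tree.edges():
        label = f" [label={_quote(_fmt(child.distance))}]" if style.show_distances else ""
        lines.append(f"  {_quote(parent.name)} -> {_quote(child.name)}{label};")
    lines.append("}")
    return "\n".join(lines) + "\n"
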