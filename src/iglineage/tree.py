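"""Rooted B-cell clonal lineage trees.

A lineage tree is a rooted tree whose nodes are immunoglobulin
variable-region sequences of one clone; edge lengths count the mutations
separating a child from its parent.  Trees arrive as Newick text (one tree
per clone, internal "hypothetical" nodes permitted and possibly unlabeled);
sequences are attached afterwards by name (see :mod:`iglineage.io_airr`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterator

import dendropy

__all__ = [
    "TreeNode",
    "LineageTree",
    "RegionMap",
    "NewickParseError",
    "imgt_region_map",
    "parse_newick",
    "to_newick",
    "REGIONS",
]

#: The six IMGT variable-domain regions in genomic order.
REGIONS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3")

#: IMGT unique-numbering nucleotide boundaries for the V region, 0-based
#: half-open: FWR1 1-78, CDR1 79-114, FWR2 115-165, CDR2 166-195,
#: FWR3 196-312 in 1-based closed coordinates; CDR3 starts at 313 with a
#: per-clone length.
IMGT_V_BOUNDS = {
    "FWR1": (0, 78),
    "CDR1": (78, 114),
    "FWR2": (114, 165),
    "CDR2": (165, 195),
    "FWR3": (195, 312),
}
CDR3_START = 312


class NewickParseError(ValueError):
    """Raised for malformed Newick input (offset/name given when known)."""


@dataclass
class TreeNode:
    """One node of a lineage tree.

    ``distance`` is the number of mutations on the edge above the node
    (0 for the root).  ``hypothetical`` is set at link time for nodes with
    no matching input record; ``populations`` may hold several labels
    (multi-population nodes).
    """

    name: str
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    distance: float = 0.0
    populations: set[str] = field(default_factory=set)
    sequence: str | None = None
    hypothetical: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"TreeNode({self.name!r}, dist={self.distance})"


class LineageTree:
    """A rooted clonal lineage tree with named nodes.

    Invariants: exactly one root; unique node names; non-negative edge
    distances.  Node order within ``children`` follows the input.
    """

    def __init__(self, clone_id: str, root: TreeNode):
        self.clone_id = clone_id
        self.root = root
        self.region_map: "RegionMap | None" = None
        self._index: dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.name in self._index:
                raise NewickParseError(
                    f"duplicate node name {node.name!r} in tree {clone_id!r}"
                )
            if node.distance < 0:
                raise ValueError(
                    f"negative branch distance on node {node.name!r}"
                )
            self._index[node.name] = node

    # -- traversal -----------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def edges(self) -> Iterator[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs in preorder."""
        for node in self.preorder():
            for child in node.children:
                yield node, child

    # -- queries -------------------------------------------------------
    @property
    def nodes(self) -> list[TreeNode]:
        return list(self.preorder())

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> TreeNode:
        return self._index[name]

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def population_universe(self) -> set[str]:
        """Union of population labels over all nodes."""
        out: set[str] = set()
        for node in self.preorder():
            out |= node.populations
        return out

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"LineageTree({self.clone_id!r}, {len(self)} nodes)"


@dataclass(frozen=True)
class RegionMap:
    """Half-open nucleotide intervals for the six variable-domain regions.

    Coordinates are 0-based positions in the (IMGT-gapped) alignment.
    Intervals must be disjoint and ordered; the CDR3 interval length equals
    ``cdr3_length``.
    """

    intervals: tuple[tuple[str, int, int], ...]
    cdr3_length: int

    def __post_init__(self):
        prev_end = 0
        for region, start, end in self.intervals:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if start < prev_end or end < start:
                raise ValueError(
                    f"region intervals must be disjoint and ordered ({region})"
                )
            prev_end = end
        cdr3 = dict((r, (s, e)) for r, s, e in self.intervals).get("CDR3")
        if cdr3 is not None and cdr3[1] - cdr3[0] != self.cdr3_length:
            raise ValueError("CDR3 interval length must equal cdr3_length")

    def region_of(self, position: int) -> str | None:
        for region, start, end in self.intervals:
            if start <= position < end:
                return region
        return None

    def interval(self, region: str) -> tuple[int, int] | None:
        for r, start, end in self.intervals:
            if r == region:
                return (start, end)
        return None

    @property
    def end(self) -> int:
        return self.intervals[-1][2]


def imgt_region_map(cdr3_length: int) -> RegionMap:
    """Region map for IMGT-gapped alignments with a per-clone CDR3 length."""
    if cdr3_length < 0:
        raise ValueError("cdr3_length must be >= 0")
    ivals = [(r, s, e) for r, (s, e) in IMGT_V_BOUNDS.items()]
    if cdr3_length:
        ivals.append(("CDR3", CDR3_START, CDR3_START + cdr3_length))
    return RegionMap(tuple(ivals), cdr3_length)


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; serialisation is ours so the
# round-trip format is stable byte-for-byte).
# ---------------------------------------------------------------------------

def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced parenthesis at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} unclosed '(' at end of input "
            f"(length {len(text)})"
        )


def parse_newick(text: str, clone_id: str | None = None) -> LineageTree:
    """Parse one Newick tree into a :class:`LineageTree`.

    Missing branch lengths default to 0.  Unlabeled internal nodes are
    auto-named ``H1, H2, ...`` in preorder so that output is reproducible.
    Raises :class:`NewickParseError` on malformed input (the character
    offset is reported for unbalanced parentheses, the name for duplicate
    node names).
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick input")
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    counter = [0]

    def convert(dnode, parent: TreeNode | None) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if not label:
            counter[0] += 1
            label = f"H{counter[0]}"
        dist = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = TreeNode(name=str(label), parent=parent, distance=float(dist))
        if parent is not None:
            parent.children.append(node)
        for dchild in dnode.child_nodes():
            convert(dchild, node)
        return node

    root = convert(dtree.seed_node, None)
    root.distance = 0.0
    return LineageTree(clone_id or root.name, root)


def _fmt_dist(d: float) -> str:
    return str(int(d)) if float(d).is_integer() else repr(d)


def to_newick(tree: LineageTree) -> str:
    """Serialise a tree to Newick text (deterministic, distances kept)."""
    buf = io.StringIO()

    def write(node: TreeNode, top: bool) -> None:
        if node.children:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                write(child, False)
            buf.write(")")
        buf.write(node.name)
        if not top:
            buf.write(f":{_fmt_dist(node.distance)}")

    write(tree.root, True)
    buf.write(";")
    return buf.getvalue()
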