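"""Sequence assignment for hypothetical (unsampled) tree nodes.

Tree inference introduces internal nodes with no sampled sequence.  A
hypothetical node at zero mutation distance from a sequenced parent simply
inherits the parent's sequence; otherwise a consensus of its sequenced
children is taken.  The consensus gives priority to gaps and Ns on ties
(if N is as frequent as A at a position, N wins) so that ambiguous
positions are excluded from mutation counting rather than over-counted.
"""

from __future__ import annotations

from collections import Counter

from .io_airr import GAP
from .tree import LineageTree, TreeNode

__all__ = ["consensus_sequence", "resolve_hypothetical"]


def consensus_sequence(
    sequences: list[str],
    tiebreak: str | None = None,
    ambiguous_ties: bool = False,
) -> str:
    """Position-wise majority consensus with gap/N priority on ties.

    Ties among maximal-count symbols resolve as gap > N > ``tiebreak``
    symbol (if given and among the tied candidates) > alphabetically
    first base, making the result independent of input order.  When an
    internal node is reconstructed from its children, passing the parent
    sequence as ``tiebreak`` keeps tied sites ancestral, so ambiguity is
    not converted into spurious mutations; with ``ambiguous_ties`` a base
    tie that the tiebreak cannot settle becomes ``N`` — the symbol
    mutation counting already excludes — instead of an arbitrary base.
    All sequences must have equal length (the offending index is
    reported).
    """
    if not sequences:
        raise ValueError("consensus of an empty sequence list")
    length = len(sequences[0])
    for i, seq in enumerate(sequences):
        if len(seq) != length:
            raise ValueError(
                f"consensus input {i} has length {len(seq)}, expected {length}"
            )
    if tiebreak is not None and len(tiebreak) != length:
        raise ValueError(
            f"tiebreak sequence has length {len(tiebreak)}, expected {length}"
        )
    out = []
    for pos in range(length):
        counts = Counter(seq[pos] for seq in sequences)
        best = max(counts.values())
        top = {sym for sym, c in counts.items() if c == best}
        if GAP in top:
            out.append(GAP)
        elif "N" in top:
            out.append("N")
        elif len(top) > 1 and tiebreak is not None and tiebreak[pos] in top:
            out.append(tiebreak[pos])
        elif len(top) > 1 and ambiguous_ties:
            out.append("N")
        else:
            out.append(min(top))
    return "".join(out)


def _nearest_sequenced_descendants(node: TreeNode) -> list[str]:
    """Sequences of the closest (by level) sequenced descendants."""
    frontier = list(node.children)
    while frontier:
        seqs = [n.sequence for n in frontier if n.sequence is not None]
        if seqs:
            return seqs
        frontier = [c for n in frontier for c in n.children]
    return []


def resolve_hypothetical(tree: LineageTree) -> dict[str, int]:
    """Assign a sequence to every node lacking one.

    Runs alternating root-to-leaf and leaf-to-root sweeps until a fixed
    point: zero-distance nodes inherit a sequenced parent's sequence,
    others take the consensus of their sequenced children; any remainder
    falls back to the consensus of its nearest sequenced descendants.
    Idempotent on fully sequenced trees.  Raises if the tree carries no
    sequence at all.  Returns resolution statistics.
    """
    if all(n.sequence is None for n in tree.preorder()):
        raise ValueError(
            f"tree {tree.clone_id!r}: no sequenced node, resolution impossible"
        )
    stats = {"inherited": 0, "consensus": 0, "fallback": 0}

    def zero_copy(node: TreeNode) -> bool:
        return (
            node.parent is not None
            and node.distance == 0
            and node.parent.sequence is not None
        )

    changed = True
    while changed:
        changed = False
        # root-to-leaf: zero-distance nodes inherit the parent's sequence
        for node in tree.preorder():
            if node.sequence is None and zero_copy(node):
                node.sequence = node.parent.sequence
                stats["inherited"] += 1
                changed = True
        # leaf-to-root: consensus of sequenced children (children are
        # visited first, so the child set is as complete as possible)
        for node in tree.postorder():
            if node.sequence is not None:
                continue
            child_seqs = [c.sequence for c in node.children if c.sequence is not None]
            if child_seqs:
                parent_seq = node.parent.sequence if node.parent else None
                node.sequence = consensus_sequence(
                    child_seqs, tiebreak=parent_seq, ambiguous_ties=True
                )
                stats["consensus"] += 1
                changed = True
    for node in tree.preorder():
        if node.sequence is None:
            seqs = _nearest_sequenced_descendants(node)
            if not seqs and node.parent is not None and node.parent.sequence:
                seqs = [node.parent.sequence]
            if not seqs:
                raise ValueError(
                    f"tree {tree.clone_id!r}: node {node.name!r} unreachable "
                    "from any sequenced node"
                )
            node.sequence = consensus_sequence(seqs)
            stats["fallback"] += 1
    return stats
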