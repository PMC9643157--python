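"""Population / time-point transition analysis on lineage trees.

Nodes carry population or time-point labels (germinal center, memory,
plasma cell, sampling day, ...), either parsed from node names or given
as an explicit node-to-label table.  Every edge whose endpoints carry
different labels implies a transition; its "transition distance" is the
mutation count on that edge.  When a temporal order of labels is given,
edges running from a later to an earlier label are flagged "impossible"
— artifacts of parsimony tree inference, informative in themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tree import LineageTree

__all__ = [
    "TransitionRecord",
    "assign_populations",
    "enumerate_transitions",
    "transition_summary",
    "co_membership",
]


@dataclass(frozen=True)
class TransitionRecord:
    tree_id: str
    source: str
    destination: str
    distance: float
    impossible: bool = False


def assign_populations(
    trees: LineageTree | list[LineageTree],
    vocabulary: set[str] | None = None,
    delimiter: str = "_",
    mapping: dict[str, set[str]] | None = None,
) -> int:
    """Fill every node's population label set.

    Either ``mapping`` (node name -> labels) or name parsing is used: the
    node name is split on ``delimiter`` and components found in
    ``vocabulary`` become labels.  Multi-population nodes carry several
    labels; unrecognised nodes get the empty set.  Raises if no node in
    the whole input received a label (likely misconfiguration).  Returns
    the number of labeled nodes.
    """
    if isinstance(trees, LineageTree):
        trees = [trees]
    if mapping is None and vocabulary is None:
        raise ValueError("provide a vocabulary or an explicit mapping")
    n_labeled = 0
    for tree in trees:
        for node in tree.preorder():
            if mapping is not None:
                labels = set(mapping.get(node.name, ()))
            else:
                labels = {
                    part for part in node.name.split(delimiter) if part in vocabulary
                }
            node.populations = labels
            if labels:
                n_labeled += 1
    if n_labeled == 0:
        raise ValueError(
            "no node matched any population label; check the delimiter, "
            "vocabulary or mapping table"
        )
    return n_labeled


def enumerate_transitions(tree: LineageTree) -> list[TransitionRecord]:
    """One record per ordered label pair (p, q), p != q, on each edge.

    Multi-label endpoints fan out into all ordered cross pairs, each
    carrying the full edge distance (deduplicate downstream if needed);
    edges whose endpoints share all labels contribute nothing.
    """
    records = []
    for parent, child in tree.edges():
        for p in sorted(parent.populations):
            for q in sorted(child.populations):
                if p != q:
                    records.append(
                        TransitionRecord(tree.clone_id, p, q, child.distance)
                    )
    return records


def co_membership(tree: LineageTree) -> list[tuple[str, str, str]]:
    """Unordered label pairs co-occurring in single nodes (zero-distance
    co-membership), reported separately from transitions."""
    out = []
    for node in tree.preorder():
        labels = sorted(node.populations)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                out.append((tree.clone_id, a, b))
    return out


def transition_summary(
    records: list[TransitionRecord],
    label_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per ordered pair: count and distance distribution (median, quartiles).

    With ``label_order`` (earliest first), records whose source comes
    after their destination are flagged impossible and summarized in
    separate rows.  A record label absent from the order is an error.
    Empty input yields an empty frame.
    """
    cols = ["source", "destination", "impossible", "count",
            "median_distance", "q1_distance", "q3_distance"]
    if not records:
        return pd.DataFrame(columns=cols)
    rank = None
    if label_order is not None:
        rank = {lab: i for i, lab in enumerate(label_order)}
        for rec in records:
            for lab in (rec.source, rec.destination):
                if lab not in rank:
                    raise ValueError(f"label {lab!r} absent from the supplied order")
    rows = []
    for rec in records:
        impossible = bool(rank and rank[rec.source] > rank[rec.destination])
        rows.append(
            {
                "source": rec.source,
                "destination": rec.destination,
                "distance": rec.distance,
                "impossible": impossible,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for (src, dst, imp), sub in df.groupby(
        ["source", "destination", "impossible"], sort=True
    ):
        q = sub["distance"].quantile([0.25, 0.5, 0.75])
        out.append(
            {
                "source": src,
                "destination": dst,
                "impossible": imp,
                "count": len(sub),
                "median_distance": q.loc[0.5],
                "q1_distance": q.loc[0.25],
                "q3_distance": q.loc[0.75],
            }
        )
    return pd.DataFrame(out, columns=cols)
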