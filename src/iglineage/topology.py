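"""Tree-shape (topology) metrics for clonal lineage trees.

Lineage-tree shapes reflect germinal-center dynamics: branching degree and
path lengths correlate with selection strength and initial affinity.  The
classic analysis computes seven shape variables per tree; here these are
node count, leaf count, root out-degree, trunk length (root to first
branching node) and the minimum/average/maximum root-to-leaf distance.
The metric set is a registry, so alternates can be swapped in without
changing the interface.  Path lengths use edge distances (mutation
counts) by default; hop counts are available via ``use_distances=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import pandas as pd

from .tree import LineageTree, TreeNode

__all__ = ["TopologyMetrics", "compute_topology", "summarize_topology",
           "METRIC_REGISTRY"]

METRIC_NAMES = (
    "nodes",
    "leaves",
    "root_degree",
    "trunk_length",
    "min_path",
    "avg_path",
    "max_path",
)


@dataclass(frozen=True)
class TopologyMetrics:
    """The seven shape variables of one tree."""

    tree_id: str
    nodes: int
    leaves: int
    root_degree: int
    trunk_length: float
    min_path: float
    avg_path: float
    max_path: float

    def validate(self) -> None:
        assert self.leaves <= self.nodes
        assert self.min_path <= self.avg_path <= self.max_path

    def to_row(self) -> dict:
        self.validate()
        return {"tree_id": self.tree_id, **{m: getattr(self, m) for m in METRIC_NAMES}}


def _root_leaf_paths(tree: LineageTree, use_distances: bool) -> list[float]:
    paths = []

    def walk(node: TreeNode, acc: float) -> None:
        if node.is_leaf:
            paths.append(acc)
            return
        for child in node.children:
            walk(child, acc + (child.distance if use_distances else 1))

    walk(tree.root, 0.0)
    # single-node tree: the root is its only leaf, path 0
    return paths or [0.0]


def _trunk_length(tree: LineageTree, use_distances: bool) -> float:
    """Distance from the root to the first branching (out-degree >= 2) node.

    Along a pure chain (no branching node) the whole path is trunk.
    """
    node = tree.root
    acc = 0.0
    while len(node.children) == 1:
        child = node.children[0]
        acc += child.distance if use_distances else 1
        node = child
    return acc


METRIC_REGISTRY: dict[str, Callable[[LineageTree, bool], float]] = {
    "nodes": lambda t, d: len(t),
    "leaves": lambda t, d: len(t.leaves) if len(t) > 1 else 1,
    "root_degree": lambda t, d: len(t.root.children),
    "trunk_length": _trunk_length,
    "min_path": lambda t, d: min(_root_leaf_paths(t, d)),
    "avg_path": lambda t, d: sum(_root_leaf_paths(t, d)) / len(_root_leaf_paths(t, d)),
    "max_path": lambda t, d: max(_root_leaf_paths(t, d)),
}


def compute_topology(tree: LineageTree, use_distances: bool = True) -> TopologyMetrics:
    """Compute the registered shape variables for one tree."""
    paths = _root_leaf_paths(tree, use_distances)
    metrics = TopologyMetrics(
        tree_id=tree.clone_id,
        nodes=len(tree),
        leaves=len(tree.leaves) if len(tree) > 1 else 1,
        root_degree=len(tree.root.children),
        trunk_length=_trunk_length(tree, use_distances),
        min_path=min(paths),
        avg_path=sum(paths) / len(paths),
        max_path=max(paths),
    )
    metrics.validate()
    return metrics


def summarize_topology(
    metrics: list[TopologyMetrics],
    group_labels: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group quartiles of every variable plus a pairwise long table.

    The long table lists every ordered pair of variables per tree
    (scatter-plot ready).  Summaries are independent of record order.
    """
    if not metrics:
        raise ValueError("no topology records to summarize")
    if group_labels is None:
        group_labels = ["all"] * len(metrics)
    if len(group_labels) != len(metrics):
        raise ValueError("one group label per record required")
    rows = [{**m.to_row(), "group": g} for m, g in zip(metrics, group_labels)]
    df = pd.DataFrame(rows).sort_values(["group", "tree_id"]).reset_index(drop=True)
    summaries = []
    for grp, sub in df.groupby("group", sort=True):
        for var in METRIC_NAMES:
            q = sub[var].quantile([0.25, 0.5, 0.75])
            summaries.append(
                {
                    "group": grp,
                    "variable": var,
                    "n": len(sub),
                    "q1": q.loc[0.25],
                    "median": q.loc[0.5],
                    "q3": q.loc[0.75],
                    "mean": sub[var].mean(),
                }
            )
    summary = pd.DataFrame(summaries)
    pair_rows = []
    for _, row in df.iterrows():
        for a, b in combinations(METRIC_NAMES, 2):
            pair_rows.append(
                {
                    "group": row["group"],
                    "tree_id": row["tree_id"],
                    "x_variable": a,
                    "y_variable": b,
                    "x": row[a],
                    "y": row[b],
                }
            )
    return summary, pd.DataFrame(pair_rows)
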