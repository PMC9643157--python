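"""Selecting lineage trees by size and population composition.

Comparative analyses often need only trees of certain populations or
sizes.  Population gates: AND keeps trees whose nodes cover all given
populations; OR keeps trees touching at least one; NOT keeps trees that
lack all of them.  Size bounds (nodes/leaves, hypothetical nodes
included) apply conjunctively.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path

from .tree import LineageTree

__all__ = ["FilterSpec", "filter_trees", "copy_selected"]

GATES = ("AND", "OR", "NOT")


@dataclass(frozen=True)
class FilterSpec:
    min_nodes: int | None = None
    max_nodes: int | None = None
    min_leaves: int | None = None
    max_leaves: int | None = None
    gate: str | None = None
    populations: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.gate is not None:
            if self.gate not in GATES:
                raise ValueError(f"unknown gate {self.gate!r}; use one of {GATES}")
            if not self.populations:
                raise ValueError("a population gate requires a non-empty set")
        for lo, hi, what in (
            (self.min_nodes, self.max_nodes, "nodes"),
            (self.min_leaves, self.max_leaves, "leaves"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"contradictory {what} bounds: min {lo} > max {hi}")


def _passes(tree: LineageTree, spec: FilterSpec) -> bool:
    n_nodes = len(tree)
    n_leaves = len(tree.leaves) if n_nodes > 1 else 1
    if spec.min_nodes is not None and n_nodes < spec.min_nodes:
        return False
    if spec.max_nodes is not None and n_nodes > spec.max_nodes:
        return False
    if spec.min_leaves is not None and n_leaves < spec.min_leaves:
        return False
    if spec.max_leaves is not None and n_leaves > spec.max_leaves:
        return False
    if spec.gate is not None:
        universe = tree.population_universe()
        if spec.gate == "AND":
            return spec.populations <= universe
        if spec.gate == "OR":
            return bool(spec.populations & universe)
        return not (spec.populations & universe)  # NOT
    return True


def filter_trees(trees: list[LineageTree], spec: FilterSpec) -> list[str]:
    """Ids of the trees passing the size bounds and population gate."""
    return [t.clone_id for t in trees if _passes(t, spec)]


def copy_selected(
    selected: list[str], source_dir: str | Path, target_dir: str | Path
) -> int:
    """Copy the Newick files of selected trees to a new directory."""
    src, dst = Path(source_dir), Path(target_dir)
    dst.mkdir(parents=True, exist_ok=True)
    n = 0
    for tree_id in selected:
        for ext in (".nw", ".newick", ".nwk"):
            f = src / f"{tree_id}{ext}"
            if f.exists():
                shutil.copy(f, dst / f.name)
                n += 1
                break
    return n
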