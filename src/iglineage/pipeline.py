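"""End-to-end per-clone analysis and repertoire-scale execution.

The mutation pipeline for one clone is: link records to nodes by name,
resolve hypothetical nodes (zero-distance inheritance / gap-N-priority
consensus), install the clone-consensus CDR3 at the root, then profile
every edge.  Repertoires are processed tree-by-tree, in parallel if
requested; per-tree failures are logged and skipped without aborting the
run, and results are sorted by tree id so output is identical at any
worker count.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd
from joblib import Parallel, delayed

from .consensus import resolve_hypothetical
from .io_airr import CloneRecords, link_nodes
from .mutations import (
    MutationProfile,
    install_clone_cdr3_consensus,
    profile_columns,
    profile_tree,
)
from .tree import LineageTree, imgt_region_map, parse_newick, to_newick

__all__ = [
    "analyze_clone",
    "run_mutation_analysis",
    "profiles_to_frame",
    "events_to_frame",
]

logger = logging.getLogger("iglineage")

EVENT_COLUMNS = ["tree_id", "parent", "child", "position", "region",
                 "from_base", "to_base", "kind", "effect", "from_aa", "to_aa"]


def analyze_clone(
    tree: LineageTree,
    records: CloneRecords,
    delimiter: str = "_",
    keep_events: bool = False,
) -> MutationProfile:
    """Run the full mutation pipeline on one parsed tree."""
    link_nodes(tree, records, delimiter=delimiter)
    resolve_hypothetical(tree)
    if tree.region_map is None:
        tree.region_map = imgt_region_map(records.cdr3_length or 0)
    if tree.region_map.interval("CDR3") is not None and records.cdr3:
        install_clone_cdr3_consensus(tree, records)
    return profile_tree(tree, keep_events=keep_events)


def _analyze_one(
    newick: str,
    clone_id: str,
    records: CloneRecords,
    delimiter: str,
    keep_events: bool,
):
    try:
        tree = parse_newick(newick, clone_id=clone_id)
        return analyze_clone(tree, records, delimiter, keep_events), None
    except Exception as exc:
        return None, f"{clone_id}: {exc}"


def run_mutation_analysis(
    trees: Sequence[LineageTree],
    clones: dict[str, CloneRecords] | CloneRecords,
    workers: int = 1,
    delimiter: str = "_",
    keep_events: bool = False,
) -> tuple[list[MutationProfile], list[str]]:
    """Profile every tree of a repertoire.

    ``clones`` maps clone id to its records (AIRR input) or is a single
    record group shared by all trees (FASTA input).  Returns profiles
    sorted by tree id plus the skip reasons for failed trees.
    """
    jobs = []
    skipped: list[str] = []
    for tree in trees:
        if isinstance(clones, CloneRecords):
            rec = clones
        else:
            rec = clones.get(tree.clone_id)
        if rec is None:
            skipped.append(f"{tree.clone_id}: no clone records")
            continue
        jobs.append((to_newick(tree), tree.clone_id, rec))
    if workers == 1:
        results = [
            _analyze_one(nw, cid, rec, delimiter, keep_events)
            for nw, cid, rec in jobs
        ]
    else:
        results = Parallel(n_jobs=workers)(
            delayed(_analyze_one)(nw, cid, rec, delimiter, keep_events)
            for nw, cid, rec in jobs
        )
    profiles = []
    for prof, reason in results:
        if prof is None:
            skipped.append(reason)
            logger.warning("skipped tree: %s", reason)
        else:
            profiles.append(prof)
    profiles.sort(key=lambda p: p.tree_id)
    return profiles, sorted(skipped)


def profiles_to_frame(profiles: Sequence[MutationProfile]) -> pd.DataFrame:
    """Per-tree profile rows in stable column order, sorted by tree id."""
    rows = [p.to_row() for p in sorted(profiles, key=lambda p: p.tree_id)]
    return pd.DataFrame(rows, columns=profile_columns())


def events_to_frame(profiles: Sequence[MutationProfile]) -> pd.DataFrame:
    """Long-format table of individual mutation events."""
    rows = []
    for prof in sorted(profiles, key=lambda p: p.tree_id):
        for ev in prof.events:
            rows.append(
                {
                    "tree_id": ev.tree_id,
                    "parent": ev.parent_name,
                    "child": ev.child_name,
                    "position": ev.position,
                    "region": ev.region,
                    "from_base": ev.from_base,
                    "to_base": ev.to_base,
                    "kind": ev.kind,
                    "effect": ev.effect,
                    "from_aa": ev.from_aa,
                    "to_aa": ev.to_aa,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
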