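"""Tree-based somatic hypermutation counting and classification.

Mutations are counted on lineage-tree edges (parent vs child sequence),
not against a single germline, so successive and reversion mutations at
one site are all observed.  Each mutation is characterised by alignment
position, IMGT region (FWR1..CDR3), source/destination nucleotide,
transition/transversion, replacement/silent, and — for replacements — the
IMGT physicochemical class change of the encoded amino acids.

CDR3 mutations are measured against the clone's consensus CDR3 (installed
at the tree root before traversal), so only SHM-generated changes are
counted, not the junctional N/P diversity present at clone founding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .aminoacids import CLASS_SYSTEMS, classify_amino_change
from .consensus import consensus_sequence
from .io_airr import GAP, CloneRecords
from .tree import REGIONS, LineageTree, RegionMap

__all__ = [
    "MutationEvent",
    "MutationProfile",
    "clone_cdr3_consensus",
    "install_clone_cdr3_consensus",
    "enumerate_edge_mutations",
    "profile_tree",
    "aggregate_profiles",
    "germline_comparison_counts",
    "profile_columns",
]

BASES = "ACGT"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

_table = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"


def _is_transition(a: str, b: str) -> bool:
    return {a, b} <= PURINES or {a, b} <= PYRIMIDINES


@dataclass(frozen=True)
class MutationEvent:
    """One nucleotide substitution on one tree edge."""

    tree_id: str
    parent_name: str
    child_name: str
    position: int  # 0-based alignment coordinate
    region: str
    from_base: str
    to_base: str
    kind: str  # "transition" | "transversion"
    effect: str  # "replacement" | "silent" | "nonclassifiable"
    from_aa: str | None = None
    to_aa: str | None = None
    property_changes: dict = field(default_factory=dict, hash=False, compare=False)


def clone_cdr3_consensus(records: CloneRecords) -> str:
    """Consensus (gap/N-priority) of the clone's CDR3 segments.

    This is the clone-level putative germline CDR3: junctional diversity
    present since clone founding is identical across the clone and cancels
    out, so only SHM-generated CDR3 changes remain countable.
    """
    cdr3s = sorted(records.cdr3.values())
    if not cdr3s:
        raise ValueError(f"clone {records.clone_id!r} has no CDR3 segments")
    lengths = {len(c) for c in cdr3s}
    if len(lengths) > 1:
        raise ValueError(
            f"clone {records.clone_id!r} has unequal CDR3 lengths {sorted(lengths)}"
            " (clone assignment violated)"
        )
    return consensus_sequence(cdr3s)


def install_clone_cdr3_consensus(tree: LineageTree, records: CloneRecords) -> str:
    """Replace the root's CDR3 segment with the clone consensus CDR3.

    Must run after every node carries a sequence and before profiling.
    Returns the installed consensus.
    """
    if tree.region_map is None:
        raise ValueError(f"tree {tree.clone_id!r} has no region map")
    ival = tree.region_map.interval("CDR3")
    cons = clone_cdr3_consensus(records)
    if ival is None:
        return cons
    start, end = ival
    root_seq = tree.root.sequence
    if root_seq is None:
        raise ValueError("root carries no sequence; resolve the tree first")
    if len(cons) != end - start:
        raise ValueError(
            f"consensus CDR3 length {len(cons)} does not match region map "
            f"interval {end - start}"
        )
    tree.root.sequence = root_seq[:start] + cons + root_seq[end:]
    return cons


def _codon_at(seq: str, position: int, region_map: RegionMap) -> tuple[int, str]:
    """Codon start and codon string containing ``position``.

    Codons are framed from alignment start; CDR3 codons are framed from
    the CDR3 interval start so the per-clone junction stays in frame.
    """
    ival = region_map.interval("CDR3")
    if ival is not None and ival[0] <= position < ival[1]:
        start = ival[0] + 3 * ((position - ival[0]) // 3)
    else:
        start = 3 * (position // 3)
    return start, seq[start : start + 3]


def enumerate_edge_mutations(
    parent_seq: str,
    child_seq: str,
    region_map: RegionMap,
    tree_id: str = "",
    parent_name: str = "",
    child_name: str = "",
) -> list[MutationEvent]:
    """All substitutions between a parent and child sequence.

    Positions where either symbol is N or a gap are not counted (ambiguity
    must not inflate counts).  Each substitution in a multi-hit codon is
    classified independently by placing it alone into the parent codon.
    Codons containing N/gap, incomplete codons and stop codons yield
    effect="nonclassifiable" (still counted in totals and regions).
    """
    if len(parent_seq) != len(child_seq):
        raise ValueError(
            f"edge {parent_name!r}->{child_name!r}: sequence lengths differ "
            f"({len(parent_seq)} vs {len(child_seq)})"
        )
    events: list[MutationEvent] = []
    for pos in range(len(parent_seq)):
        a, b = parent_seq[pos], child_seq[pos]
        if a == b or a not in BASES or b not in BASES:
            continue
        region = region_map.region_of(pos)
        if region is None:
            continue
        kind = "transition" if _is_transition(a, b) else "transversion"
        cstart, codon = _codon_at(parent_seq, pos, region_map)
        effect = "nonclassifiable"
        from_aa = to_aa = None
        props: dict = {}
        if len(codon) == 3 and all(c in BASES for c in codon):
            offset = pos - cstart
            mutated = codon[:offset] + b + codon[offset + 1 :]
            from_aa = CODON_TO_AA[codon]
            to_aa = CODON_TO_AA[mutated]
            if from_aa == "*" or to_aa == "*":
                effect = "nonclassifiable"
                from_aa = to_aa = None
            elif from_aa == to_aa:
                effect = "silent"
            else:
                effect = "replacement"
                props = classify_amino_change(from_aa, to_aa)
        events.append(
            MutationEvent(
                tree_id=tree_id,
                parent_name=parent_name,
                child_name=child_name,
                position=pos,
                region=region,
                from_base=a,
                to_base=b,
                kind=kind,
                effect=effect,
                from_aa=from_aa,
                to_aa=to_aa,
                property_changes=props,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Per-tree aggregation
# ---------------------------------------------------------------------------

def _class_columns() -> list[str]:
    cols = []
    for system, table in CLASS_SYSTEMS.items():
        classes = sorted(set(table.values()))
        for cls in classes:
            cols.append(f"{system}_source_{cls}")
        for cls in classes:
            cols.append(f"{system}_dest_{cls}")
    return cols


def profile_columns() -> list[str]:
    """Stable column order of the per-tree mutation-profile CSV."""
    cols = ["tree_id", "sequences", "nodes", "mutations", "mutations_per_sequence"]
    cols += [r.lower() for r in REGIONS]
    cols += ["transitions", "transversions", "replacements", "silents",
             "nonclassifiable"]
    for r in REGIONS:
        cols += [f"{r.lower()}_r", f"{r.lower()}_s"]
    cols += [f"source_{b.lower()}" for b in BASES]
    cols += [f"dest_{b.lower()}" for b in BASES]
    cols += _class_columns()
    return cols


@dataclass
class MutationProfile:
    """Aggregated mutation counts of one lineage tree (one CSV row)."""

    tree_id: str
    sequences: int
    nodes: int
    counts: dict[str, float]
    events: list[MutationEvent] = field(default_factory=list, repr=False)

    @property
    def total(self) -> int:
        return int(self.counts["mutations"])

    def validate(self) -> None:
        c = self.counts
        total = c["mutations"]
        assert sum(c[r.lower()] for r in REGIONS) == total
        assert c["transitions"] + c["transversions"] == total
        assert c["replacements"] + c["silents"] + c["nonclassifiable"] == total
        if self.sequences:
            assert abs(c["mutations_per_sequence"] - total / self.sequences) < 1e-12

    def to_row(self) -> dict[str, float | str]:
        self.validate()
        row: dict[str, float | str] = {
            "tree_id": self.tree_id,
            "sequences": self.sequences,
            "nodes": self.nodes,
        }
        row.update(self.counts)
        return row


def profile_tree(
    tree: LineageTree,
    region_map: RegionMap | None = None,
    keep_events: bool = False,
) -> MutationProfile:
    """Traverse every edge of a fully sequenced tree and aggregate counts.

    ``sequences`` counts sampled (non-hypothetical) nodes.  Branch lengths
    play no role here: counts always derive from the sequences.
    """
    rmap = region_map or tree.region_map
    if rmap is None:
        raise ValueError(f"tree {tree.clone_id!r} has no region map")
    counts: dict[str, float] = {
        col: 0 for col in profile_columns() if col not in ("tree_id", "sequences", "nodes")
    }
    all_events: list[MutationEvent] = []
    for parent, child in tree.edges():
        if parent.sequence is None or child.sequence is None:
            raise ValueError(
                f"tree {tree.clone_id!r}: node without sequence on edge "
                f"{parent.name!r}->{child.name!r} (resolve the tree first)"
            )
        events = enumerate_edge_mutations(
            parent.sequence, child.sequence, rmap,
            tree_id=tree.clone_id, parent_name=parent.name, child_name=child.name,
        )
        for ev in events:
            counts["mutations"] += 1
            counts[ev.region.lower()] += 1
            counts["transitions" if ev.kind == "transition" else "transversions"] += 1
            if ev.effect == "replacement":
                counts["replacements"] += 1
                counts[f"{ev.region.lower()}_r"] += 1
                for system, (src, dst) in ev.property_changes.items():
                    counts[f"{system}_source_{src}"] += 1
                    counts[f"{system}_dest_{dst}"] += 1
            elif ev.effect == "silent":
                counts["silents"] += 1
                counts[f"{ev.region.lower()}_s"] += 1
            else:
                counts["nonclassifiable"] += 1
            counts[f"source_{ev.from_base.lower()}"] += 1
            counts[f"dest_{ev.to_base.lower()}"] += 1
        if keep_events:
            all_events.extend(events)
    n_nodes = len(tree)
    n_seq = sum(1 for n in tree.preorder() if not n.hypothetical)
    counts["mutations_per_sequence"] = (
        counts["mutations"] / n_seq if n_seq else 0.0
    )
    profile = MutationProfile(
        tree_id=tree.clone_id,
        sequences=n_seq,
        nodes=n_nodes,
        counts=counts,
        events=all_events,
    )
    profile.validate()
    return profile


def aggregate_profiles(
    profiles: list[MutationProfile],
    group_labels: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repertoire summary across trees, optionally split into groups.

    Returns ``(summary, long)``: per-group means/medians of totals and
    per-region mutation fractions (pooled region count over pooled total,
    the repertoire-level distribution), plus a box-plot-ready long table
    of per-tree values.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    if group_labels is None:
        group_labels = ["all"] * len(profiles)
    if len(group_labels) != len(profiles):
        raise ValueError("one group label per profile required")
    rows = []
    for prof, grp in zip(profiles, group_labels):
        row = prof.to_row()
        row["group"] = grp
        rows.append(row)
    df = pd.DataFrame(rows)
    summaries = []
    for grp, sub in df.groupby("group", sort=True):
        total = sub["mutations"].sum()
        entry: dict[str, float | str] = {
            "group": grp,
            "trees": len(sub),
            "mean_mutations": sub["mutations"].mean(),
            "median_mutations": sub["mutations"].median(),
            "mean_mutations_per_sequence": sub["mutations_per_sequence"].mean(),
        }
        for r in REGIONS:
            entry[f"{r.lower()}_fraction"] = (
                sub[r.lower()].sum() / total if total else 0.0
            )
        summaries.append(entry)
    summary = pd.DataFrame(summaries)
    value_cols = ["mutations", "mutations_per_sequence"] + [r.lower() for r in REGIONS]
    long = df.melt(
        id_vars=["group", "tree_id"],
        value_vars=value_cols,
        var_name="variable",
        value_name="value",
    )
    return summary, long


def germline_comparison_counts(
    sequences: list[str], germline: str
) -> dict[str, float]:
    """Sequence-based (non-tree) mutation counts for comparison.

    ``representative``: mutations of each observed sequence vs the
    germline (min/max over choices of representative); ``consensus``:
    mutations of the observed-sequence consensus vs the germline.  Used to
    contrast with tree-based counting, which also sees successive and
    reversion mutations.
    """
    def hamming(a: str, b: str) -> int:
        return sum(
            1
            for x, y in zip(a, b)
            if x != y and x in BASES and y in BASES
        )

    per_seq = [hamming(s, germline) for s in sequences]
    cons = consensus_sequence(sequences)
    return {
        "representative_min": min(per_seq),
        "representative_max": max(per_seq),
        "consensus": hamming(cons, germline),
        "consensus_sequence": cons,
    }
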