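"""Reading AIRR Rearrangement tables and FASTA, and linking them to trees.

Sequences can be given as an AIRR/Change-O tab-separated table (IMGT-gapped
``sequence_alignment`` columns) or as a FASTA file keyed by node name.
``link_nodes`` attaches each record to the tree node of the same name; nodes
with no matching record are flagged hypothetical and later resolved by
:mod:`iglineage.consensus`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .tree import LineageTree, parse_newick

__all__ = [
    "CloneRecords",
    "read_airr_table",
    "read_fasta",
    "link_nodes",
    "normalize_sequence",
    "cdr3_length_from_junction",
    "load_trees",
]

logger = logging.getLogger("iglineage")

#: mandatory AIRR Rearrangement columns (junction may be replaced by cdr3)
MANDATORY = ("sequence_id", "sequence_alignment", "clone_id")

GAP = "-"


def normalize_sequence(seq: str) -> str:
    """Uppercase and normalise gap characters ('.' IMGT and '-') to '-'."""
    return seq.upper().replace(".", GAP)


def cdr3_length_from_junction(junction: str) -> int:
    """CDR3 length from an AIRR junction: the junction includes the two
    conserved flanking codons, so cdr3 = junction minus 6 nt."""
    return max(len(junction) - 6, 0)


@dataclass
class CloneRecords:
    """Sequence records of one clone, keyed by sequence_id."""

    clone_id: str
    sequences: dict[str, str]
    cdr3: dict[str, str] = field(default_factory=dict)
    germline: str | None = None
    cdr3_length: int | None = None
    gapped: bool = True

    def __len__(self) -> int:
        return len(self.sequences)


def read_airr_table(path: str | Path) -> dict[str, CloneRecords]:
    """Read an AIRR Rearrangement TSV and group records by clone.

    Requires ``sequence_id``, ``sequence_alignment``, ``clone_id`` and a
    ``cdr3`` or ``junction`` column (cdr3 takes precedence for the per-clone
    CDR3 length).  Raises ``ValueError`` naming any missing column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"empty AIRR table: {path}")
    for col in MANDATORY:
        if col not in df.columns:
            raise ValueError(f"AIRR table missing mandatory column: {col}")
    if "cdr3" not in df.columns and "junction" not in df.columns:
        raise ValueError("AIRR table missing mandatory column: junction (or cdr3)")

    clones: dict[str, CloneRecords] = {}
    for clone_id, grp in df.groupby("clone_id", sort=True):
        seqs: dict[str, str] = {}
        cdr3s: dict[str, str] = {}
        lengths: set[int] = set()
        germline = None
        for row in grp.itertuples(index=False):
            sid = str(row.sequence_id)
            seqs[sid] = normalize_sequence(str(row.sequence_alignment))
            if "cdr3" in df.columns and getattr(row, "cdr3", ""):
                cdr3 = normalize_sequence(str(row.cdr3))
                cdr3s[sid] = cdr3
                lengths.add(len(cdr3))
            elif "junction" in df.columns and getattr(row, "junction", ""):
                junction = normalize_sequence(str(row.junction))
                lengths.add(cdr3_length_from_junction(junction))
                cdr3s[sid] = junction[3:-3] if len(junction) > 6 else ""
            if germline is None and "germline_alignment" in df.columns:
                g = str(getattr(row, "germline_alignment", ""))
                if g:
                    germline = normalize_sequence(g)
        clones[str(clone_id)] = CloneRecords(
            clone_id=str(clone_id),
            sequences=seqs,
            cdr3=cdr3s,
            germline=germline,
            cdr3_length=(sorted(lengths)[-1] if lengths else None),
            gapped="germline_alignment" in df.columns
            or any(GAP in s or "." in s for s in seqs.values()),
        )
    return clones


def read_fasta(path: str | Path, clone_id: str = "fasta") -> CloneRecords:
    """Read node-keyed FASTA into a single record group."""
    seqs = {
        rec.id: normalize_sequence(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return CloneRecords(clone_id=clone_id, sequences=seqs, gapped=False)


def link_nodes(
    tree: LineageTree,
    records: CloneRecords,
    delimiter: str = "_",
) -> int:
    """Attach each record's sequence to the node of the same name.

    A node name may concatenate several collapsed sequence ids (and/or
    population labels) with ``delimiter``; any component matching a record
    id links the node.  Two matching ids with different sequences raise an
    error.  Unmatched nodes are flagged hypothetical.  Returns the number
    of hypothetical nodes; if no node at all matched, a warning is logged
    and ``ValueError`` raised so the tree can be skipped with a reason.
    """
    n_hypo = 0
    n_linked = 0
    for node in tree.preorder():
        matched: list[str] = []
        if node.name in records.sequences:
            matched = [node.name]
        elif delimiter and delimiter in node.name:
            matched = [
                part
                for part in node.name.split(delimiter)
                if part in records.sequences
            ]
        if matched:
            seqs = {records.sequences[m] for m in matched}
            if len(seqs) > 1:
                raise ValueError(
                    f"node {node.name!r} matches records with conflicting "
                    f"sequences: {sorted(matched)}"
                )
            node.sequence = seqs.pop()
            node.hypothetical = False
            n_linked += 1
        else:
            node.sequence = None
            node.hypothetical = True
            n_hypo += 1
    if n_linked == 0:
        logger.warning(
            "tree %s: no node matched any sequence record; skipping",
            tree.clone_id,
        )
        raise ValueError(f"no sequence record matched any node of tree {tree.clone_id!r}")
    return n_hypo


def load_trees(path: str | Path) -> list[LineageTree]:
    """Load Newick trees from a file or a directory of ``*.nw``/``*.newick``
    files (a directory input processes every tree file inside)."""
    p = Path(path)
    if p.is_dir():
        files = sorted(
            list(p.glob("*.nw")) + list(p.glob("*.newick")) + list(p.glob("*.nwk"))
        )
        if not files:
            raise FileNotFoundError(f"no *.nw/*.newick files in directory {p}")
        return [parse_newick(f.read_text(), clone_id=f.stem) for f in files]
    text = p.read_text()
    trees = []
    chunks = [c.strip() for c in text.replace("\r\n", "\n").split(";") if c.strip()]
    for i, chunk in enumerate(chunks):
        cid = p.stem if len(chunks) == 1 else f"{p.stem}_{i + 1}"
        trees.append(parse_newick(chunk + ";", clone_id=cid))
    return trees
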