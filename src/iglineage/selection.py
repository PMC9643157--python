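"""Export of CDR3-inclusive mutation counts for selection analysis.

Selection-strength estimators compare observed replacement/silent (R/S)
counts in CDRs vs FWRs with the expectation under no selection.  Because
tree-based counting measures CDR3 mutations against the clone consensus
CDR3, the CDR3 can be included — which requires a per-tree region
definition, since every clone has its own CDR3 length.  This module
builds the per-tree table such estimators consume: R/S counts for the
CDR group (CDR1+CDR2+CDR3) and FWR group (FWR1+FWR2+FWR3), the clonal
germline (with the consensus CDR3 installed) and the CDR3 length.
"""

from __future__ import annotations

import pandas as pd

from .io_airr import CloneRecords
from .mutations import MutationProfile, clone_cdr3_consensus
from .tree import CDR3_START

__all__ = ["build_selection_table", "SELECTION_COLUMNS"]

SELECTION_COLUMNS = [
    "sequence_id",
    "clonal_germline",
    "cdr3_length",
    "region_boundary",
    "mu_count_cdr_r",
    "mu_count_cdr_s",
    "mu_count_fwr_r",
    "mu_count_fwr_s",
]

CDR_GROUP = ("CDR1", "CDR2", "CDR3")
FWR_GROUP = ("FWR1", "FWR2", "FWR3")


def build_selection_table(
    profiles: list[MutationProfile],
    clones: dict[str, CloneRecords],
    exclude_cdr3: bool = False,
) -> pd.DataFrame:
    """One row per tree, ready for a downstream selection estimator.

    The clonal germline is the clone's germline alignment with the CDR3
    segment replaced by the clone consensus CDR3; ``region_boundary`` is
    the per-tree alignment end of the variable domain (FWR3 end +
    cdr3_length, 1-based), i.e. the region-definition parameter adjusted
    to each tree's own CDR3 length.  ``exclude_cdr3`` drops only the CDR3
    contributions from the CDR group (for comparison runs).
    """
    rows = []
    for prof in profiles:
        rec = clones.get(prof.tree_id)
        if rec is None:
            raise ValueError(f"no clone records/germline for tree {prof.tree_id!r}")
        if rec.germline is None:
            raise ValueError(f"clone {prof.tree_id!r} has no germline alignment")
        cons = clone_cdr3_consensus(rec)
        cdr3_len = len(cons)
        germ = rec.germline
        if len(germ) >= CDR3_START:
            germ = germ[:CDR3_START] + cons + germ[CDR3_START + cdr3_len:]
        cdr_regions = [r for r in CDR_GROUP if not (exclude_cdr3 and r == "CDR3")]
        c = prof.counts
        rows.append(
            {
                "sequence_id": prof.tree_id,
                "clonal_germline": germ,
                "cdr3_length": cdr3_len,
                "region_boundary": CDR3_START + cdr3_len,
                "mu_count_cdr_r": int(sum(c[f"{r.lower()}_r"] for r in cdr_regions)),
                "mu_count_cdr_s": int(sum(c[f"{r.lower()}_s"] for r in cdr_regions)),
                "mu_count_fwr_r": int(sum(c[f"{r.lower()}_r"] for r in FWR_GROUP)),
                "mu_count_fwr_s": int(sum(c[f"{r.lower()}_s"] for r in FWR_GROUP)),
            }
        )
    return pd.DataFrame(rows, columns=SELECTION_COLUMNS)
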