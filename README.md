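# iglineage

Lineage tree-based analysis of immunoglobulin (Ig) heavy-chain variable-region
gene repertoires: tree-aware somatic hypermutation (SHM) counting and
classification, tree-shape metrics, population/time-point transition analysis,
tree filtering, DOT rendering, and export of CDR3-inclusive replacement/silent
counts for downstream selection analysis.

## The problem and who this is for

During an immune response, activated B cells diversify their B-cell receptor
genes by SHM and are selected for antigen affinity.  The sequences of one
clone form a rooted **lineage tree**: nodes are variable-region sequences,
edges carry the mutations separating a child from its parent.  Most mutation
analyses compare each sequence with a single putative germline — which
collapses parallel origins, successive hits on the same site and reversions,
and cannot see CDR3 mutations at all (the germline CDR3 of a single sequence
is, by construction, identical to the sequence).  Counting **on the tree**
fixes both problems:

- every edge is an observed parent→child step, so successive and reversion
  mutations are individually counted;
- CDR3 changes are measured against the **clone-consensus CDR3** — the
  clone-level putative germline junction — so junctional N/P diversity present
  since clone founding cancels out and only SHM-generated CDR3 changes remain.

The package is a library (plus a thin `iglineage` command-line tool) for
computational immunologists working with AIRR-seq repertoires: it consumes
Newick trees (one per clone, internal hypothetical nodes permitted) and
AIRR Rearrangement TSV or node-keyed FASTA sequences.

## The method in brief

For one clone with tree `T` and records `R`:

1. **Link** each record to the node of the same name; unmatched nodes are
   *hypothetical*.
2. **Resolve** every hypothetical node: at zero mutation distance from a
   sequenced parent the node inherits the parent's sequence; otherwise it
   takes a position-wise consensus of its sequenced children with priority
   gaps > N on ties (ambiguity becomes a symbol that mutation counting
   excludes, never a spurious base).
3. **Install** the clone-consensus CDR3 at the root.
4. **Profile** every edge: for each position where parent and child differ
   (neither symbol N or gap) record position, IMGT region (FWR1, CDR1, FWR2,
   CDR2, FWR3, CDR3 under IMGT unique numbering, with a per-clone CDR3
   length), source/target nucleotide, transition/transversion, and
   replacement/silent by single-substitution codon translation; replacements
   additionally get the IMGT physicochemical class change (charge,
   hydropathy, volume, chemical, hydrogen donor/acceptor, polarity).

Per-tree profiles satisfy `Σ region counts = transitions + transversions =
replacements + silents + nonclassifiable = total` and feed the repertoire
summaries, the selection-table export (R/S counts for CDR1+2+3 and
FWR1+2+3 with a per-tree region boundary = FWR3 end + CDR3 length), the
MTree-style topology metrics (nodes, leaves, root degree, trunk length,
min/avg/max root-to-leaf distance), transition statistics with
impossible-transition flags, AND/OR/NOT tree filters, and DOT drawings.

A synthetic-clone simulator plants every mutation explicitly (Poisson-like
per-site process with CDR targeting and transition bias, plus an
N/P-diversification step at clone founding), so every analysis has an exact
ground-truth oracle.

## Worked example

```bash
python examples/01_count_mutations.py
```

```
germline:                 AGT
observed consensus:       AAT
consensus vs germline:    1 mutation
representative range:     1-2 mutations
tree-based count:         4 mutations
```

A four-sequence, one-codon clone descending from germline `AGT`: comparing a
representative sequence with the germline finds 1–2 mutations and the
observed-sequence consensus (`AAT`) finds 1, but the tree contains 4 point
mutations — two parallel `G→A` origins, one forward and one reversion change.
Only the tree-based count is exact.

The other scripts in `examples/` each demonstrate one capability end to end
(full pipeline vs planted truth, topology metrics, transition analysis with
impossible flags, filtering + DOT, selection export, repertoire simulation).

Command-line equivalents:

```bash
iglineage simulate --out fixtures --n 10 --seed 1
iglineage mutations --trees fixtures/trees --airr fixtures/cell0_airr.tsv --out results
iglineage mtree --trees fixtures/trees --out results
```

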