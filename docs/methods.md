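# Methods

This note documents the models, conventions, numerical choices and known
limitations of `iglineage`.

## Model and assumptions

A clonal lineage tree is a rooted tree whose nodes are Ig variable-region
sequences of one clone and whose edge lengths count nucleotide substitutions
between parent and child.  The package assumes:

- trees are supplied (Newick), one per clone — tree inference, clone
  assignment and V/D/J annotation are upstream of this package;
- sequences are equal-length alignments per clone (IMGT-gapped V+J with the
  clone's CDR3 in place); insertions/deletions are represented as gap
  characters and never called as events;
- branch lengths are only trusted for the zero-distance inheritance rule and
  for edge labels; **all mutation counts derive from sequences**, never from
  branch lengths.

## Region definitions

Alignment coordinates follow IMGT unique numbering for the V region, as
fixed nucleotide intervals (1-based closed on disk, 0-based half-open
internally): FWR1 1–78, CDR1 79–114, FWR2 115–165, CDR2 166–195,
FWR3 196–312, CDR3 from 313 with a per-clone length.  The CDR3 length is
taken from the AIRR `cdr3` column when present, else `junction` length minus
6 nt (the junction includes the two conserved flanking codons).  Positions
outside the mapped intervals (e.g. FWR4/J tail) are not counted.  Codons are
framed as `floor(position/3)` except inside the CDR3, which is framed from
its own interval start so the junction stays in frame for any clone.

## Hypothetical-node resolution

Tree inference introduces internal nodes without sampled sequences.
Resolution runs to a fixed point:

1. root-to-leaf: a node at zero distance from a sequenced parent inherits
   the parent's sequence verbatim;
2. leaf-to-root: any other unresolved node takes the position-wise consensus
   of its sequenced children (children are visited first, so the child set
   is as complete as possible); a final fallback uses the nearest sequenced
   descendants.

Consensus ties resolve gap > N > parent base (when the parent sequence is
known) > alphabetical.  In reconstruction, a base tie the parent cannot
settle becomes `N`.  The rationale is asymmetry of errors: a wrongly
reconstructed base creates spurious mutations on *every* adjacent edge,
whereas an `N` merely excludes one site from counting on those edges.  The
leaf-to-root ordering matters for the same reason — taking a consensus over
a partial child set converts sampling gaps into reconstruction errors that
inflate counts.  With these rules, recovered totals never exceeded planted
totals in 2,000 simulated clones with 30% of internal nodes unsampled
(97% recovered exactly); with an order-insensitive alphabetical tie-break
instead, 2–20% of clones over-counted.  The clone-level CDR3 consensus (a
consensus of *sampled* sequences, not a reconstruction) keeps the plain
gap > N > alphabetical rule.

## Mutation classification

One event per aligned position where parent and child differ and neither
symbol is N or gap.  Transitions are purine↔purine or pyrimidine↔pyrimidine
changes.  For amino-acid effect, each substitution in a multi-hit codon is
evaluated by placing it **alone** into the parent codon (the standard R/S
convention; events stay independent).  Codons containing N/gap, incomplete
codons, and stop codons on either side are `nonclassifiable` — still counted
in totals and region counts, but carrying no amino-acid record.  Replacement
events are annotated with the source and destination class in six IMGT
physicochemical class systems (charge, hydropathy, volume, chemical,
hydrogen donor/acceptor, polarity).

## Clone-consensus CDR3 at the root

Before profiling, the root's CDR3 segment is replaced by the consensus of
the clone's sampled CDR3s.  This is the clone-level putative germline
junction: N/P diversity present since clone founding is shared by the whole
clone and cancels out, so only SHM-generated CDR3 changes are counted.  The
installation is an explicit pipeline step rather than part of `profile_tree`
so that trees with a trusted root sequence (e.g. the one-codon worked
example, or simulations with a known founder) can be profiled as-is.

## Topology metrics

The seven per-tree shape variables are: node count, leaf count, root
out-degree, trunk length (summed edge distance from the root to the first
node with out-degree ≥ 2; along a pure chain the whole path), and
minimum/average/maximum root-to-leaf distance.  Path lengths use edge
distances (mutation counts) by default; hop counts are available via a
flag.  The metric set is exposed as a registry so alternative variable
sets can be swapped in without changing any interface.  A single-node tree
is its own leaf with all path metrics 0.

## Transitions

Each edge whose endpoints carry different population/time-point labels
yields one record per ordered label pair (p, q), p ≠ q, carrying the full
edge distance; multi-label endpoints fan out into all cross pairs (users
may deduplicate downstream).  Only direct edges are considered — a label
change across an unlabeled intermediate node is *not* bridged into a single
transition.  Label co-occurrence within one node is reported separately as
zero-distance co-membership, not as a transition.  With a supplied temporal
order, records whose source follows their destination are flagged
impossible; they are summarized separately rather than suppressed, because
their distance distribution is itself diagnostic of parsimony-inference
artifacts.

## Synthetic-clone generator

The generator is the package's study-condition definition and exact oracle;
it emulates an antibody-repertoire simulation with CDR-focused SHM and
transition bias, not any particular tool's event model.

Defaults (chosen once as realistic study conditions):

| parameter | default | meaning |
|---|---|---|
| cdr3_length | 36 nt | typical heavy-chain CDR3 (12 aa); germline = 312 + 36 nt |
| generations | 3 | tree depth |
| branching | 3 per internal node | modestly bushy clone (40 nodes) |
| shm_probability | 0.8 | per-edge probability of undergoing SHM at all |
| change_probability | 0.003 /nt | per-site substitution probability on an SHM edge |
| cdr_multiplier | 4 | CDR1/2/3 per-site rate multiplier (SHM targeting) |
| transition_bias | 3 | transition target weight vs each transversion (60% transitions) |
| np_diversification | 2 | CDR3 substitutions planted on root-outgoing edges at founding |
| unsampled_internal_fraction | 0.3 | internal nodes without records (leaves always sampled) |

The germline is drawn from sense codons (stop-free in frame), so
nonclassifiable events arise only from mutation.  Every substitution is
recorded (edge, position, region, bases, transition/transversion); edge
lengths equal planted event counts, so zero-distance inheritance is
exercised.  A constant branching factor of 3 reflects that sampled clonal
trees used for mutation analysis are rarely pure chains, and gives internal
nodes enough sequenced neighbours for majority reconstruction — with
branching 2 every reconstruction decision at an unsampled node is a
coin-flip tie, which no tie rule can make informative.

The N/P-diversification step plants a fixed small number of CDR3
substitutions on the root's first outgoing edges, modelling junctional
variants present at clone founding.  This creates the junction-diversity
floor that drives the CDR3-fraction trend: as the SHM change probability
falls, total mutations shrink toward the constant floor and the CDR3's
share of all mutations rises.  The simulator re-draws a clone (derived
seed, deterministic) in the rare case that the sampled-CDR3 consensus
differs from the founder CDR3, so planted events remain an exact oracle for
the full pipeline.

What the generator does **not** emulate: indels, hotspot-motif (WRC/GYW)
targeting, per-read collapsing weights, sequencing error, clone-size
distributions, or phylogenetic inference error beyond unsampled nodes.
Passing tests therefore demonstrate correctness of counting, resolution and
bookkeeping on clean planted data — not robustness to annotation or
tree-inference errors in real repertoires.

## Problem sizes and determinism

The validation suite uses 300 clones (3 settings × 100) for exact-oracle
equivalence, 100 clones for conservativeness, a 5-point rate sweep at 100
clones per point (rates 0.00025–0.004 /nt) for trend direction, 1,000
random trees (≤ 50 nodes) for the topology oracle, and 100 random
configurations each for filter-gate identities and transition bookkeeping —
sizes at which the checked properties are already tight while the whole
suite runs in well under a minute.  All randomness flows from explicit
seeds; repertoire outputs are sorted by tree id before writing, so CSV and
DOT outputs are byte-identical across runs and worker counts.

## Known limitations

- Replacement/silent calls on multi-hit codons follow the
  single-substitution convention; joint-codon interpretations would differ.
- Whether collapsed duplicate reads should weight an edge is not modelled:
  each edge counts once.
- The consensus spans immediate children (nearest sequenced descendants as
  fallback), not all descendants; both choices are defensible and the
  difference is confined to nodes with unsampled children.
- The selection estimator itself is not included; the package exports the
  per-tree count table (`sequence_id`, clonal germline with consensus CDR3,
  CDR3 length, per-tree region boundary, CDR/FWR R and S counts) that such
  estimators consume, with an `--exclude-cdr3` toggle for comparison runs.
- Rendering stops at DOT text; rasterisation is delegated to an external
  renderer.
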