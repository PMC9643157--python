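"""Selecting trees by population composition and rendering one to DOT."""

from iglineage import (
    DotStyle,
    FilterSpec,
    assign_populations,
    filter_trees,
    parse_newick,
    tree_to_dot,
)

newicks = {
    "T1": "(S1_NAV:1,S2_GC:2)R1;",
    "T2": "(S3_GC:1)R2;",
    "T3": "(S4_MEM:3)R3;",
}
trees = [parse_newick(nw, clone_id=tid) for tid, nw in newicks.items()]
assign_populations(trees, vocabulary={"NAV", "GC", "MEM", "PC"})

print("AND{NAV,GC}:", filter_trees(trees, FilterSpec(gate="AND", populations=frozenset({"NAV", "GC"}))))
print("OR{NAV,MEM}:", filter_trees(trees, FilterSpec(gate="OR", populations=frozenset({"NAV", "MEM"}))))
print("NOT{GC}:    ", filter_trees(trees, FilterSpec(gate="NOT", populations=frozenset({"GC"}))))
print()
dot = tree_to_dot(trees[0], DotStyle(palette={"NAV": "gold", "GC": "seagreen"}))
print(dot)
print("Filled DOT nodes are sampled sequences (colored by population);")
print("edge labels are mutation counts, ready for a DOT renderer.")
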