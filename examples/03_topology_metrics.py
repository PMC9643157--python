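"""Tree-shape metrics: the seven variables of one lineage tree.

Shape properties (branching at the root, trunk length, path lengths)
reflect the germinal-center dynamics that produced the clone.
"""

from iglineage import compute_topology, parse_newick

tree = parse_newick("(((L1:2,L2:1)B:1,L3:4)A:2)root;")
m = compute_topology(tree)

print(f"nodes={m.nodes} leaves={m.leaves} root_degree={m.root_degree}")
print(f"trunk_length={m.trunk_length} (mutations from root to the first branch)")
print(f"root-to-leaf distances: min={m.min_path} avg={m.avg_path:.2f} max={m.max_path}")
print()
print("A long trunk with shallow branching suggests a late, focused")
print("expansion; bushy shallow trees suggest early diversification.")
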