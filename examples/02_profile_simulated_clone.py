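"""Full mutation pipeline on a simulated clone with planted ground truth.

The simulator plants every mutation explicitly, so the pipeline result
(link records to nodes, resolve hypothetical nodes, install the clone
consensus CDR3 at the root, profile every edge) can be compared with the
exact truth.
"""

from iglineage import SimulationParams, analyze_clone, parse_newick, simulate_clone

params = SimulationParams(unsampled_internal_fraction=0.3)
clone = simulate_clone(params, seed=7, clone_id="demo")

tree = parse_newick(clone.newick, clone_id="demo")
profile = analyze_clone(tree, clone.records)

print(f"tree: {len(tree)} nodes, {profile.sequences} sampled, "
      f"{clone.n_unsampled} hypothetical")
print(f"planted mutations:   {len(clone.truth)}")
print(f"recovered mutations: {profile.total}")
print("per-region counts:  ",
      {r: int(profile.counts[r]) for r in
       ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3")})
print(f"transitions/transversions: {int(profile.counts['transitions'])}"
      f"/{int(profile.counts['transversions'])}")
print()
print("With 30% of internal nodes unsampled, the gap/N-prioritised")
print("consensus keeps the recovered total at or below the planted truth —")
print("ambiguity is never converted into spurious mutations.")
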