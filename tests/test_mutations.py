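"""Mutation enumeration, classification, and per-tree profiling."""

import numpy as np
import pytest

from iglineage import (
    CloneRecords,
    SimulationParams,
    aggregate_profiles,
    analyze_clone,
    classify_amino_change,
    clone_cdr3_consensus,
    enumerate_edge_mutations,
    germline_comparison_counts,
    imgt_region_map,
    one_codon_example,
    parse_newick,
    profile_tree,
    simulate_clone,
)
from iglineage.tree import RegionMap

ALL_FWR = RegionMap((("FWR1", 0, 300),), 0)


class TestEnumerateEdgeMutations:
    def test_identical_sequences_give_no_events(self):
        assert enumerate_edge_mutations("AAA", "AAA", ALL_FWR) == []

    def test_replacement_transition(self):
        # AAA (Lys) -> AGA (Arg): one transition, replacement
        (ev,) = enumerate_edge_mutations("AAA", "AGA", ALL_FWR)
        assert (ev.position, ev.from_base, ev.to_base) == (1, "A", "G")
        assert ev.kind == "transition"
        assert ev.effect == "replacement"
        assert (ev.from_aa, ev.to_aa) == ("K", "R")

    def test_silent_transition(self):
        # AAA (Lys) -> AAG (Lys): silent
        (ev,) = enumerate_edge_mutations("AAA", "AAG", ALL_FWR)
        assert ev.effect == "silent"
        assert ev.kind == "transition"
        assert ev.property_changes == {}

    def test_transversion_classified(self):
        (ev,) = enumerate_edge_mutations("AAA", "ACA", ALL_FWR)
        assert ev.kind == "transversion"

    def test_n_and_gap_positions_not_counted(self):
        assert enumerate_edge_mutations("ANA", "AGA", ALL_FWR) == []
        assert enumerate_edge_mutations("A-A", "ACA", ALL_FWR) == []

    def test_codon_with_n_is_nonclassifiable_but_counted(self):
        (ev,) = enumerate_edge_mutations("AAN", "AGN", ALL_FWR)
        assert ev.effect == "nonclassifiable"

    def test_stop_codon_is_nonclassifiable(self):
        # TAA is a stop: the event is counted but carries no amino acids
        (ev,) = enumerate_edge_mutations("TAC", "TAA", ALL_FWR)
        assert ev.effect == "nonclassifiable"
        assert ev.from_aa is None and ev.to_aa is None

    def test_multi_hit_codon_substitutions_classified_independently(self):
        # AAA -> GGA: each change placed alone into the parent codon
        evs = enumerate_edge_mutations("AAA", "GGA", ALL_FWR)
        assert [(e.from_aa, e.to_aa) for e in evs] == [("K", "E"), ("K", "R")]

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="lengths differ"):
            enumerate_edge_mutations("AAA", "AAAA", ALL_FWR)

    def test_region_attribution_uses_map(self):
        rmap = imgt_region_map(6)
        seq = "A" * 318
        child = seq[:80] + "G" + seq[81:]  # inside CDR1 (78..114)
        (ev,) = enumerate_edge_mutations(seq, child, rmap)
        assert ev.region == "CDR1"
        child = seq[:313] + "G" + seq[314:]  # inside CDR3
        (ev,) = enumerate_edge_mutations(seq, child, rmap)
        assert ev.region == "CDR3"


class TestClassifyAminoChange:
    def test_lys_to_arg_conserves_charge_and_polarity(self):
        props = classify_amino_change("K", "R")
        assert props["charge"] == ("positive", "positive")
        assert props["polarity"] == ("polar", "polar")

    def test_asp_to_ala_changes_charge_and_hydropathy(self):
        props = classify_amino_change("D", "A")
        assert props["charge"] == ("negative", "neutral")
        assert props["hydropathy"] == ("hydrophilic", "hydrophobic")

    def test_all_six_class_systems_reported(self):
        props = classify_amino_change("F", "Y")
        assert set(props) == {
            "charge", "hydropathy", "volume", "chemical", "hydrogen", "polarity",
        }

    def test_nonstandard_amino_acid_rejected(self):
        with pytest.raises(ValueError):
            classify_amino_change("K", "*")


class TestCloneCdr3Consensus:
    def test_singleton_clone_is_verbatim(self):
        rec = CloneRecords("c", sequences={"S1": "X"}, cdr3={"S1": "AATGGT"})
        assert clone_cdr3_consensus(rec) == "AATGGT"

    def test_one_codon_clone_consensus_is_aat(self):
        ex = one_codon_example()
        gc = germline_comparison_counts(
            sorted(ex.records.sequences.values()), "AGT"
        )
        assert gc["consensus_sequence"] == "AAT"

    def test_unequal_cdr3_lengths_error(self):
        rec = CloneRecords(
            "c", sequences={}, cdr3={"S1": "AAT", "S2": "AATG"}
        )
        with pytest.raises(ValueError, match="unequal CDR3 lengths"):
            clone_cdr3_consensus(rec)

    def test_low_rate_consensus_recovers_founder_cdr3(self):
        clone = simulate_clone(SimulationParams(), seed=5, clone_id="c")
        founder = clone.tree.root.sequence[312:]
        assert clone_cdr3_consensus(clone.records) == founder


class TestProfileTree:
    def test_single_node_tree_all_zero(self):
        tree = parse_newick("A;")
        tree["A"].sequence = "AAA"
        prof = profile_tree(tree, region_map=ALL_FWR)
        assert prof.total == 0

    def test_one_codon_clone_counts_four_tree_mutations(self):
        """Tree traversal sees all 4 planted changes where germline
        comparison sees only 1 (consensus) or 1-2 (representative)."""
        ex = one_codon_example()
        prof = profile_tree(ex.tree)
        assert prof.total == 4
        gc = germline_comparison_counts(
            sorted(ex.records.sequences.values()), "AGT"
        )
        assert gc["consensus"] == 1
        assert (gc["representative_min"], gc["representative_max"]) == (1, 2)

    def test_reversion_chain_counts_two_where_germline_sees_zero(self):
        # A -> G -> A along a path: tree counts 2, tip-vs-germline counts 0
        tree = parse_newick("((S2:1)S1:1)R;")
        tree["R"].sequence = "AAA"
        tree["S1"].sequence = "AGA"
        tree["S2"].sequence = "AAA"
        prof = profile_tree(tree, region_map=ALL_FWR)
        assert prof.total == 2
        gc = germline_comparison_counts(["AAA"], "AAA")
        assert gc["representative_max"] == 0

    def test_planted_events_recovered_exactly(self):
        params = SimulationParams(unsampled_internal_fraction=0.0)
        clone = simulate_clone(params, seed=21, clone_id="c")
        tree = parse_newick(clone.newick, clone_id="c")
        prof = analyze_clone(tree, clone.records)
        assert prof.total == len(clone.truth)
        truth_by_region = clone.truth["region"].value_counts().to_dict()
        for region in ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3"):
            assert prof.counts[region.lower()] == truth_by_region.get(region, 0)

    def test_profile_invariants_hold_on_simulated_clones(self):
        for seed in range(10):
            clone = simulate_clone(
                SimulationParams(), seed=400 + seed, clone_id=f"c{seed}"
            )
            tree = parse_newick(clone.newick, clone_id=clone.clone_id)
            prof = analyze_clone(tree, clone.records)
            c = prof.counts
            assert c["transitions"] + c["transversions"] == prof.total
            assert (
                c["replacements"] + c["silents"] + c["nonclassifiable"]
                == prof.total
            )
            assert sum(
                c[r] for r in ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3")
            ) == prof.total

    def test_unsequenced_node_raises(self):
        tree = parse_newick("(S1:1)R;")
        tree["R"].sequence = "AAA"
        with pytest.raises(ValueError, match="without sequence"):
            profile_tree(tree, region_map=ALL_FWR)


class TestAggregateProfiles:
    def _profiles(self, seeds):
        out = []
        for s in seeds:
            clone = simulate_clone(SimulationParams(), seed=s, clone_id=f"c{s}")
            tree = parse_newick(clone.newick, clone_id=clone.clone_id)
            out.append(analyze_clone(tree, clone.records))
        return out

    def test_single_profile_summary_is_identity(self):
        (prof,) = self._profiles([50])
        summary, _ = aggregate_profiles([prof])
        assert summary.loc[0, "mean_mutations"] == prof.total
        assert summary.loc[0, "median_mutations"] == prof.total

    def test_mean_over_two_profiles(self):
        profs = self._profiles([51, 52])
        summary, _ = aggregate_profiles(profs)
        assert summary.loc[0, "mean_mutations"] == pytest.approx(
            (profs[0].total + profs[1].total) / 2
        )

    def test_region_fractions_sum_to_one(self):
        profs = self._profiles(range(60, 66))
        summary, _ = aggregate_profiles(profs, ["g1", "g2", "g1", "g2", "g1", "g2"])
        frac_cols = [f"{r}_fraction" for r in
                     ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3")]
        assert np.allclose(summary[frac_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            aggregate_profiles([])
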