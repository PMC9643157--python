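"""The synthetic-clone generator and its planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from iglineage import (
    SimulationParams,
    analyze_clone,
    link_nodes,
    parse_newick,
    simulate_clone,
    sweep,
)


class TestSimulateClone:
    def test_zero_change_probability_gives_germline_everywhere(self):
        params = SimulationParams(
            change_probability=0.0, shm_probability=0.0, np_diversification=0
        )
        clone = simulate_clone(params, seed=1)
        germ = clone.tree.root.sequence
        assert all(n.sequence == germ for n in clone.tree.preorder())
        assert len(clone.truth) == 0
        tree = parse_newick(clone.newick, clone_id=clone.clone_id)
        assert analyze_clone(tree, clone.records).total == 0

    def test_edge_distances_equal_planted_event_counts(self):
        clone = simulate_clone(SimulationParams(), seed=2)
        per_edge = clone.truth.groupby(["parent", "child"]).size()
        for parent, child in clone.tree.edges():
            assert child.distance == per_edge.get((parent.name, child.name), 0)

    def test_hypothetical_count_matches_planted_unsampled(self):
        clone = simulate_clone(SimulationParams(), seed=3)
        tree = parse_newick(clone.newick, clone_id=clone.clone_id)
        n_hypo = link_nodes(tree, clone.records)
        assert n_hypo == clone.n_unsampled

    def test_leaves_always_sampled(self):
        clone = simulate_clone(SimulationParams(unsampled_internal_fraction=1.0),
                               seed=4)
        for node in clone.tree.preorder():
            if node.is_leaf:
                assert not node.hypothetical

    def test_deterministic_given_seed(self):
        a = simulate_clone(SimulationParams(), seed=5)
        b = simulate_clone(SimulationParams(), seed=5)
        assert a.newick == b.newick
        assert a.records.sequences == b.records.sequences
        assert a.truth.equals(b.truth)

    def test_cdr_targeting_raises_cdr_fraction(self):
        """Focusing SHM on the CDRs must raise the CDR share of events."""
        def cdr_fraction(mult, seeds):
            cdr = tot = 0
            for s in seeds:
                clone = simulate_clone(
                    SimulationParams(cdr_multiplier=mult, np_diversification=0),
                    seed=s,
                )
                cdr += clone.truth["region"].isin(["CDR1", "CDR2", "CDR3"]).sum()
                tot += len(clone.truth)
            return cdr / tot

        seeds = range(100, 160)
        assert cdr_fraction(10.0, seeds) > cdr_fraction(1.0, seeds)

    def test_transition_bias_raises_transition_share(self):
        def ts_share(bias, seeds):
            ts = tot = 0
            for s in seeds:
                clone = simulate_clone(
                    SimulationParams(transition_bias=bias), seed=s
                )
                ts += (clone.truth["kind"] == "transition").sum()
                tot += len(clone.truth)
            return ts / tot

        seeds = range(200, 240)
        assert ts_share(10.0, seeds) > ts_share(1.0, seeds)

    def test_np_diversification_plants_cdr3_events_at_founding(self):
        params = SimulationParams(
            change_probability=0.0, shm_probability=0.0, np_diversification=2
        )
        clone = simulate_clone(params, seed=6)
        assert len(clone.truth) == 2
        assert set(clone.truth["region"]) == {"CDR3"}
        assert set(clone.truth["parent"]) == {"N0"}

    def test_airr_frame_round_trips_through_reader(self, tmp_path):
        from iglineage import read_airr_table

        clone = simulate_clone(SimulationParams(), seed=7, clone_id="c7")
        path = tmp_path / "airr.tsv"
        clone.airr_frame().to_csv(path, sep="\t", index=False)
        clones = read_airr_table(path)
        assert clones["c7"].sequences == clone.records.sequences
        assert clones["c7"].cdr3_length == 36


class TestSweep:
    def test_single_cell_writes_trees_airr_truth_manifest(self, tmp_path):
        manifest = sweep([SimulationParams()], 1, tmp_path, seed=9)
        assert len(manifest) == 1
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "cell0_airr.tsv").exists()
        assert (tmp_path / "cell0_truth.csv").exists()
        assert len(list((tmp_path / "trees").glob("*.nw"))) == 1

    def test_mean_mutations_per_sequence_rises_with_change_probability(self, tmp_path):
        grid = [
            SimulationParams(change_probability=p) for p in (0.0005, 0.002, 0.008)
        ]
        manifest = sweep(grid, 15, tmp_path, seed=10)
        means = manifest.groupby("cell")["n_events"].mean()
        assert means.loc[0] < means.loc[1] < means.loc[2]

    def test_empty_grid_errors(self, tmp_path):
        with pytest.raises(ValueError):
            sweep([], 5, tmp_path)
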