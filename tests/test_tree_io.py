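"""Newick parsing, AIRR/FASTA reading, and node-sequence linking."""

import textwrap

import numpy as np
import pytest

from iglineage import (
    CloneRecords,
    link_nodes,
    load_trees,
    parse_newick,
    read_airr_table,
    read_fasta,
    to_newick,
)
from iglineage.io_airr import cdr3_length_from_junction
from iglineage.tree import NewickParseError

from conftest import random_tree


class TestParseNewick:
    def test_basic_two_leaf_tree(self):
        tree = parse_newick("(A:1,B:2)R;")
        assert tree.root.name == "R"
        assert [(c.name, c.distance) for c in tree.root.children] == [
            ("A", 1.0),
            ("B", 2.0),
        ]

    def test_single_node_tree(self):
        tree = parse_newick("A;")
        assert len(tree) == 1
        assert tree.root.is_leaf
        assert sum(c.distance for c in tree.nodes) == 0

    def test_auto_named_internal_node_and_zero_edge(self):
        tree = parse_newick("((A:1,B:1):0,C:3)R;")
        assert len(tree) == 5
        assert "H1" in tree  # preorder auto-naming of unlabeled internals
        assert tree["H1"].distance == 0
        zero_edges = [c for _, c in tree.edges() if c.distance == 0]
        assert len(zero_edges) == 1

    def test_missing_branch_lengths_default_to_zero(self):
        tree = parse_newick("(A,B)R;")
        assert all(c.distance == 0 for c in tree.root.children)

    def test_underscores_preserved(self):
        tree = parse_newick("(S1_GC:1,S2_MEM:2)R;")
        assert "S1_GC" in tree

    def test_unbalanced_parentheses_reports_offset(self):
        with pytest.raises(NewickParseError, match="offset|unclosed"):
            parse_newick("((A:1,B:2)R;")
        with pytest.raises(NewickParseError, match="offset"):
            parse_newick("(A:1,B:2))R;")

    def test_duplicate_names_rejected(self):
        with pytest.raises(NewickParseError, match="A"):
            parse_newick("(A:1,A:2)R;")

    def test_roundtrip_is_isomorphic(self, rng):
        for i in range(25):
            tree = random_tree(rng, tree_id=f"T{i}")
            back = parse_newick(to_newick(tree), clone_id=tree.clone_id)
            assert to_newick(back) == to_newick(tree)
            assert {n.name for n in back.preorder()} == {
                n.name for n in tree.preorder()
            }
            for node in tree.preorder():
                assert back[node.name].distance == node.distance


class TestAirrTable:
    def _write(self, tmp_path, body):
        p = tmp_path / "airr.tsv"
        p.write_text(textwrap.dedent(body))
        return p

    def test_grouping_by_clone(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            sequence_id\tsequence_alignment\tjunction\tclone_id
            S1\tAAATTT\tTGTAAATTTGCATGG\tc1
            S2\tAAATTA\tTGTAAATTTGCATGG\tc1
            S3\tCCCGGG\tTGTCCCTGG\tc2
            """,
        )
        clones = read_airr_table(p)
        assert set(clones) == {"c1", "c2"}
        assert len(clones["c1"]) == 2
        assert len(clones["c2"]) == 1

    def test_cdr3_length_from_junction_convention(self, tmp_path):
        # a 15 nt junction strips two flanking codons -> 9 nt CDR3
        assert cdr3_length_from_junction("TGTAAATTTGCATGG") == 9
        p = self._write(
            tmp_path,
            """\
            sequence_id\tsequence_alignment\tjunction\tclone_id
            S1\tAAATTT\tTGTAAATTTGCATGG\tc1
            """,
        )
        assert read_airr_table(p)["c1"].cdr3_length == 9

    def test_cdr3_column_takes_precedence(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            sequence_id\tsequence_alignment\tjunction\tcdr3\tclone_id
            S1\tAAATTT\tTGTAAATTTGCATGG\tAAATTTGCAAAA\tc1
            """,
        )
        assert read_airr_table(p)["c1"].cdr3_length == 12

    def test_missing_clone_id_errors(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            sequence_id\tsequence_alignment\tjunction
            S1\tAAATTT\tTGTAAATTTGCATGG
            """,
        )
        with pytest.raises(ValueError, match="clone_id"):
            read_airr_table(p)

    def test_empty_table_errors(self, tmp_path):
        p = self._write(
            tmp_path,
            "sequence_id\tsequence_alignment\tjunction\tclone_id\n",
        )
        with pytest.raises(ValueError, match="empty"):
            read_airr_table(p)

    def test_reading_is_deterministic(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            sequence_id\tsequence_alignment\tjunction\tclone_id
            S1\tAAATTT\tTGTAAATTTGCATGG\tc1
            S2\tAAATTA\tTGTAAATTTGCATGG\tc1
            """,
        )
        a, b = read_airr_table(p), read_airr_table(p)
        assert a["c1"].sequences == b["c1"].sequences

    def test_crlf_tolerated(self, tmp_path):
        p = tmp_path / "crlf.tsv"
        p.write_bytes(
            b"sequence_id\tsequence_alignment\tjunction\tclone_id\r\n"
            b"S1\tAAATTT\tTGTAAATTTGCATGG\tc1\r\n"
        )
        assert len(read_airr_table(p)["c1"]) == 1


class TestLinkNodes:
    def _records(self, **seqs):
        return CloneRecords(clone_id="c1", sequences=seqs)

    def test_name_match_carries_sequence(self):
        tree = parse_newick("(S1:1)R;")
        n_hypo = link_nodes(tree, self._records(S1="AAT"))
        assert tree["S1"].sequence == "AAT"
        assert not tree["S1"].hypothetical
        assert n_hypo == 1  # the root

    def test_unlabeled_internal_becomes_hypothetical(self):
        tree = parse_newick("((S1:1,S2:1):1)R;")
        n_hypo = link_nodes(tree, self._records(S1="AAT", S2="AAC", R="AAT"))
        assert n_hypo == 1
        assert tree["H1"].hypothetical

    def test_sequenced_plus_hypothetical_covers_all_nodes(self):
        tree = parse_newick("((S1:1,S2:1):1,S3:2)R;")
        n_hypo = link_nodes(tree, self._records(S1="AAT", S2="AAC"))
        n_seq = sum(1 for n in tree.preorder() if n.sequence is not None)
        assert n_seq + n_hypo == len(tree)

    def test_collapsed_multi_id_names_link_by_component(self):
        tree = parse_newick("(S1_S2:1)R;")
        link_nodes(tree, self._records(S1="AAT", S2="AAT"))
        assert tree["S1_S2"].sequence == "AAT"

    def test_conflicting_collapsed_ids_error(self):
        tree = parse_newick("(S1_S2:1)R;")
        with pytest.raises(ValueError, match="conflicting"):
            link_nodes(tree, self._records(S1="AAT", S2="GGG"))

    def test_zero_matches_raises_for_skip(self):
        tree = parse_newick("(X1:1)R;")
        with pytest.raises(ValueError, match="no sequence record"):
            link_nodes(tree, self._records(S1="AAT"))


def test_load_trees_from_directory(tmp_path):
    (tmp_path / "a.nw").write_text("(A:1,B:2)R;\n")
    (tmp_path / "b.newick").write_text("(C:1)Q;\n")
    trees = load_trees(tmp_path)
    assert sorted(t.clone_id for t in trees) == ["a", "b"]
    with pytest.raises(FileNotFoundError):
        load_trees(tmp_path / "empty_does_not_exist_dir")


def test_read_fasta(tmp_path):
    p = tmp_path / "seqs.fa"
    p.write_text(">S1\nAAT\n>S2\naac\n")
    rec = read_fasta(p)
    assert rec.sequences == {"S1": "AAT", "S2": "AAC"}
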