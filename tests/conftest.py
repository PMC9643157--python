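"""Shared fixtures: small hand-built clones and random tree generators."""

from __future__ import annotations

import numpy as np
import pytest

from iglineage import LineageTree, TreeNode, parse_newick


def random_tree(rng: np.random.Generator, max_nodes: int = 50,
                tree_id: str = "T") -> LineageTree:
    """Random rooted tree by uniform attachment, integer edge distances."""
    n = int(rng.integers(1, max_nodes + 1))
    nodes = [TreeNode(name=f"{tree_id}_N0")]
    for i in range(1, n):
        parent = nodes[int(rng.integers(0, len(nodes)))]
        child = TreeNode(
            name=f"{tree_id}_N{i}",
            parent=parent,
            distance=float(rng.integers(0, 6)),
        )
        parent.children.append(child)
        nodes.append(child)
    return LineageTree(tree_id, nodes[0])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_tree():
    return parse_newick("((A:1,B:1)X:2,C:3)R;")
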