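"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from peroxevol.phylo import DistanceMatrix, Msa, Node, Tree


# ---------------------------------------------------------------------------
# tree oracles
# ---------------------------------------------------------------------------

def tree_path_distances(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (independent traversal)."""
    leaves = sorted(tree.leaf_names)
    idx = {name: k for k, name in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    for node in tree.root.postorder():
        if node.is_leaf:
            continue
        kids = [sorted(ch.leaf_names()) for ch in node.children]
        for ka, kb in itertools.combinations(kids, 2):
            da = walk_sub(node, set(ka))
            db = walk_sub(node, set(kb))
            for a in ka:
                for b in kb:
                    val = da[a] + db[b]
                    d[idx[a], idx[b]] = d[idx[b], idx[a]] = val
    return DistanceMatrix(leaves, d)


def walk_sub(node, targets):
    """Depth of each target leaf below ``node``."""
    out = {}

    def rec(n, acc):
        if n.is_leaf:
            if n.name in targets:
                out[n.name] = acc
            return
        for ch in n.children:
            rec(ch, acc + (ch.length or 0.0))

    rec(node, 0.0)
    return out


def four_point_additive(d: np.ndarray, tol: float = 1e-9) -> bool:
    """Four-point-condition oracle: for every quadruple the two largest of
    the three pairwise sums must be equal."""
    n = d.shape[0]
    for quad in itertools.combinations(range(n), 4):
        i, j, k, l = quad
        sums = sorted([
            d[i, j] + d[k, l],
            d[i, k] + d[j, l],
            d[i, l] + d[j, k],
        ])
        if abs(sums[2] - sums[1]) > tol:
            return False
    return True


def random_binary_tree(rng: np.random.Generator, n_taxa: int,
                       bl_range=(0.1, 1.0)) -> Tree:
    """Random rooted binary topology with uniform branch lengths (all well
    above zero, so additive reconstruction is unambiguous)."""
    tips = [Node(name=f"x{i + 1}") for i in range(n_taxa)]
    nodes = list(tips)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    tree = Tree(root)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(rng.uniform(*bl_range))
    return tree


@pytest.fixture
def additive_fixture_set():
    """Random additive 4-6 taxon matrices with their generating trees."""
    rng = np.random.default_rng(77)
    out = []
    for n_taxa in (4, 5, 6):
        for _ in range(4):
            tree = random_binary_tree(rng, n_taxa)
            out.append((tree, tree_path_distances(tree)))
    return out


@pytest.fixture
def toy_msa() -> Msa:
    return Msa({
        "a1": "ACDEFGHIKL",
        "a2": "ACDEFGHIKL",
        "b1": "ACDEWGHIKV",
        "b2": "ACDEWGHIKV",
        "c1": "MCDEWGHLKV",
    })
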