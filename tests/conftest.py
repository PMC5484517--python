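import numpy as np
import pytest

from phyloconflict.alignment import Alignment
from phyloconflict.model import lg_model
from phyloconflict.tree import PhyloTree, Node, parse_newick


@pytest.fixture(scope="session")
def model():
    return lg_model(gamma_shape=0.8)


@pytest.fixture(scope="session")
def model_flat():
    """Single-category model (no rate heterogeneity) for sharp oracles."""
    return lg_model(gamma_shape=1.0, n_categories=1)


@pytest.fixture
def toy_alignment():
    return Alignment.from_pairs([
        ("A", "ARND-C"),
        ("B", "ARNDFC"),
        ("C", "AKNEFX"),
        ("D", "GKCEFW"),
    ])


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.25):0.05);")


def random_binary_tree(rng, n_leaves, min_len=0.05, max_len=1.0,
                       names=None) -> PhyloTree:
    """Random unrooted binary topology with uniform branch lengths."""
    if names is None:
        names = [f"t{i}" for i in range(n_leaves)]
    nodes = [Node(name=nm, length=rng.uniform(min_len, max_len))
             for nm in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=rng.uniform(min_len, max_len))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = Node()
    for x in nodes:
        root.add_child(x)
    return PhyloTree(root, rooted=False)


def tree_path_distances(tree: PhyloTree):
    """Leaf-to-leaf path-length matrix (independent of NJ internals)."""
    names = sorted(tree.leaf_names())
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    D = np.zeros((n, n))

    def walk(node, dist_to_leaves):
        # returns {leaf: distance to this node}
        if node.is_leaf:
            return {node.name: 0.0}
        acc = {}
        for child in node.children:
            sub = walk(child, dist_to_leaves)
            sub = {k: v + child.length for k, v in sub.items()}
            for k1, d1 in acc.items():
                for k2, d2 in sub.items():
                    D[idx[k1], idx[k2]] = D[idx[k2], idx[k1]] = d1 + d2
            acc.update(sub)
        return acc

    walk(tree.root, {})
    return names, D
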