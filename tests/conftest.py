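import numpy as np
import pytest

from septevo.simulate import SimulationConfig, simulate_species_tree
from septevo.trees import read_newick


@pytest.fixture(scope="session")
def species_tree_small():
    """((A,B),C) with unit-ish branch lengths and labelled internals."""
    return read_newick("((A:1,B:1)AB:1,C:2)R;")


@pytest.fixture(scope="session")
def species_tree_22():
    return simulate_species_tree(22, 0.01, seed=11, root_age=1350.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def default_config():
    return SimulationConfig()


def random_rooted_tree(labels, rng, length_scale=1.0):
    """Random rooted binary tree over given leaf labels (test helper)."""
    import dendropy

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lbl in labels:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(lbl)
        nodes.append(node)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    for ch in list(root.child_nodes()):
        root.remove_child(ch)
        tree.seed_node.add_child(ch)
    if root.taxon is not None:  # single-leaf edge case
        tree.seed_node.taxon = root.taxon
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(0.1, 1.0)) * length_scale
    return tree
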