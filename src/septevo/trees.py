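"""Rooted-tree utilities: Newick I/O, support handling, rooting.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package.  Leaf labels live on ``node.taxon.label``; internal-node labels
(which Newick uses for support values or node names) live on ``node.label``.
"""

from __future__ import annotations

from typing import Iterable, Optional

import dendropy

from .errors import InvalidInputError, NotASplitError

__all__ = [
    "read_newick",
    "write_newick",
    "leaf_labels",
    "node_support",
    "is_ultrametric",
    "root_tree",
]


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick tree from a file path or a literal Newick string."""
    data = source
    if not source.lstrip().startswith("("):
        with open(source) as fh:
            data = fh.read()
    return dendropy.Tree.get(
        data=data,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def write_newick(tree: dendropy.Tree, path: Optional[str] = None) -> str:
    """Serialize a tree to Newick; deterministic for a given tree object."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def node_support(node: dendropy.Node) -> Optional[float]:
    """Support value of the edge above ``node``, normalized to [0, 1].

    Newick files carry support either as a fraction (posterior probability)
    or as a percentage (bootstrap); values > 1 are divided by 100.
    """
    label = node.label
    if label is None:
        return None
    try:
        value = float(label)
    except (TypeError, ValueError):
        return None
    return value / 100.0 if value > 1.0 else value


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    """True if all root-to-leaf path lengths agree within relative tolerance."""
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if not depths:
        return True
    top = max(depths)
    if top == 0.0:
        return True
    return (top - min(depths)) / top <= rel_tol


def _cluster_node(tree: dendropy.Tree, target: frozenset[str]) -> Optional[dendropy.Node]:
    """Find the non-root node whose descendant leaf set equals ``target``."""
    leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            acc: frozenset[str] = frozenset()
            for child in node.child_nodes():
                acc = acc | leafsets[id(child)]
            leafsets[id(node)] = acc
        if node is not tree.seed_node and leafsets[id(node)] == target:
            return node
    return None


def root_tree(
    tree: dendropy.Tree,
    method: str,
    outgroup_leaves: Optional[Iterable[str]] = None,
) -> dendropy.Tree:
    """Root (or re-root) a tree by outgroup or at the midpoint.

    ``outgroup`` places the root on the edge subtending the outgroup clade of
    the unrooted topology, splitting that edge's length in half.  ``midpoint``
    places the root at the midpoint of the longest leaf-to-leaf path.
    """
    if method not in ("outgroup", "midpoint"):
        raise InvalidInputError(f"unknown rooting method {method!r}")
    t = tree.clone(depth=1)
    if method == "midpoint":
        t.reroot_at_midpoint(update_bipartitions=False)
        t.suppress_unifurcations()
        return t

    if not outgroup_leaves:
        raise InvalidInputError("outgroup rooting requires outgroup_leaves")
    og = frozenset(outgroup_leaves)
    leaves = frozenset(leaf_labels(t))
    if not og <= leaves:
        raise InvalidInputError(f"outgroup leaves not in tree: {sorted(og - leaves)}")
    if og == leaves:
        raise NotASplitError("outgroup must be a proper subset of the leaves")

    # Work on the unrooted topology so the current root placement is irrelevant.
    t.deroot()
    node = _cluster_node(t, og)
    if node is None:
        node = _cluster_node(t, leaves - og)
    if node is None:
        raise NotASplitError(f"outgroup {sorted(og)} is not a split of the unrooted tree")
    length = node.edge.length
    half = length / 2.0 if length is not None else None
    t.reroot_at_edge(node.edge, length1=half, length2=half, update_bipartitions=False)
    t.suppress_unifurcations()
    return t
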