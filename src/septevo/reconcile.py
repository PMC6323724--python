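"""Paralog-Group assignment and gene-tree / species-tree reconciliation.

Reconciliation embeds a rooted gene tree into a rooted species tree by the
least-common-ancestor (LCA) map and reads off duplication and loss events.
Weakly supported gene-tree edges (support below a threshold, default 0.90)
are contracted first, and each resulting polytomy is resolved exhaustively
to minimize the duplication+loss score, which mirrors the rearrangement
mode of NOTUNG-style reconciliation.  All co-optimal resolutions are
returned (up to a cap) so downstream summaries can average over them, and a
per-species-branch gene copy number is computed for each resolution.

Conventions
-----------
* A species branch is identified by the label of its child node; the root
  carries a stem branch identified by the root label.
* Depth is counted in edges from the species root (root depth 0).
* Losses on a gene edge (p -> c): depth(M(c)) - depth(M(p)) - 1 if p is a
  speciation, depth(M(c)) - depth(M(p)) if p is a duplication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import dendropy

from .errors import (
    InvalidInputError,
    MappingError,
    SeptevoError,
    UnresolvedPolytomyError,
)
from .trees import node_support

__all__ = [
    "ReconciliationResult",
    "UNCLASSIFIED",
    "default_leaf_to_taxon",
    "assign_groups",
    "lca_map",
    "reconcile",
    "copy_number_profile",
]

UNCLASSIFIED = "UNCLASSIFIED"

#: Exhaustive polytomy resolution is limited to this many children
#: (7 children -> 10395 rooted binary resolutions).
DEFAULT_POLYTOMY_CAP = 7
DEFAULT_CO_OPTIMAL_CAP = 32
DEFAULT_SUPPORT_THRESHOLD = 0.90


def default_leaf_to_taxon(label: str) -> str:
    """Default parse rule for gene-leaf labels of the form ``taxon|copy``."""
    return label.split("|")[0]


@dataclass
class ReconciliationResult:
    event_map: dict[str, str]          # internal gene node label -> speciation|duplication
    n_duplications: int
    n_losses: int
    branch_copies: dict[str, int]      # species branch (child-node label) -> copies
    n_optima: int
    gene_tree_newick: str = ""
    loss_branches: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Species-tree index

class _SpeciesIndex:
    def __init__(self, species_tree: dendropy.Tree):
        self.tree = species_tree
        self.depth: dict[int, int] = {}
        self.parent: dict[int, Optional[dendropy.Node]] = {}
        self.label: dict[int, str] = {}
        self.by_taxon: dict[str, dendropy.Node] = {}
        i = 0
        for node in species_tree.preorder_node_iter():
            p = node.parent_node
            self.parent[id(node)] = p
            self.depth[id(node)] = 0 if p is None else self.depth[id(p)] + 1
            if node.is_leaf():
                self.label[id(node)] = node.taxon.label
                self.by_taxon[node.taxon.label] = node
            else:
                i += 1
                self.label[id(node)] = node.label if node.label else f"sp{i}"

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while self.depth[id(a)] > self.depth[id(b)]:
            a = self.parent[id(a)]
        while self.depth[id(b)] > self.depth[id(a)]:
            b = self.parent[id(b)]
        while a is not b:
            a = self.parent[id(a)]
            b = self.parent[id(b)]
        return a

    def path_down(self, top: dendropy.Node, bottom: dendropy.Node) -> list[dendropy.Node]:
        """Species nodes from ``top`` to ``bottom`` inclusive (top first)."""
        path = []
        node = bottom
        while node is not top:
            if node is None:
                raise MappingError("path_down: top is not an ancestor of bottom")
            path.append(node)
            node = self.parent[id(node)]
        path.append(top)
        return list(reversed(path))


def _resolve_leaf_to_taxon(
    leaf_to_taxon: Union[None, Mapping[str, str], Callable[[str], str]]
) -> Callable[[str], str]:
    if leaf_to_taxon is None:
        return default_leaf_to_taxon
    if callable(leaf_to_taxon):
        return leaf_to_taxon
    mapping = dict(leaf_to_taxon)

    def lookup(label: str) -> str:
        if label not in mapping:
            raise MappingError(f"gene leaf {label!r} has no taxon mapping")
        return mapping[label]

    return lookup


# ---------------------------------------------------------------------------
# Group assignment

def assign_groups(
    gene_tree: dendropy.Tree, anchors: Mapping[str, str]
) -> dict[str, str]:
    """Assign each gene leaf to a paralog Group by anchor leaves.

    For each Group g, the largest clade containing at least one anchor of g
    and no anchor of any other Group is found; all its leaves are assigned
    g.  Leaves covered by no such clade are UNCLASSIFIED.
    """
    leafsets: dict[int, frozenset[str]] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            acc: frozenset[str] = frozenset()
            for ch in node.child_nodes():
                acc |= leafsets[id(ch)]
            leafsets[id(node)] = acc
    all_leaves = leafsets[id(gene_tree.seed_node)]
    missing = set(anchors) - set(all_leaves)
    if missing:
        raise InvalidInputError(f"anchor leaves not in gene tree: {sorted(missing)}")

    leaf_node = {lf.taxon.label: lf for lf in gene_tree.leaf_node_iter()}
    groups = sorted(set(anchors.values()))
    assignment: dict[str, str] = {}
    claimed: dict[str, str] = {}
    for group in groups:
        own = {a for a, g in anchors.items() if g == group}
        foreign = {a for a, g in anchors.items() if g != group}
        best: Optional[frozenset[str]] = None
        for anchor in sorted(own):
            node = leaf_node[anchor]
            while node.parent_node is not None and not (
                leafsets[id(node.parent_node)] & foreign
            ):
                node = node.parent_node
            clade = leafsets[id(node)]
            if best is None or len(clade) > len(best):
                best = clade
        assert best is not None
        for leaf in best:
            if leaf in claimed and claimed[leaf] != group:
                raise SeptevoError(
                    f"leaf {leaf!r} claimed by Groups {claimed[leaf]!r} and {group!r}: "
                    "anchored clades overlap"
                )
            claimed[leaf] = group
            assignment[leaf] = group
    for leaf in sorted(all_leaves):
        assignment.setdefault(leaf, UNCLASSIFIED)
    return assignment


# ---------------------------------------------------------------------------
# LCA mapping

def lca_map(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_to_taxon: Union[None, Mapping[str, str], Callable[[str], str]] = None,
) -> dict[dendropy.Node, dendropy.Node]:
    """Map each gene-tree node to its species-tree image under the LCA map."""
    index = _SpeciesIndex(species_tree)
    to_taxon = _resolve_leaf_to_taxon(leaf_to_taxon)
    images: dict[dendropy.Node, dendropy.Node] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            taxon = to_taxon(node.taxon.label)
            if taxon not in index.by_taxon:
                raise MappingError(
                    f"gene leaf {node.taxon.label!r}: taxon {taxon!r} not in species tree"
                )
            images[node] = index.by_taxon[taxon]
        else:
            children = node.child_nodes()
            img = images[children[0]]
            for ch in children[1:]:
                img = index.lca(img, images[ch])
            images[node] = img
    return images


# ---------------------------------------------------------------------------
# Polytomy resolution

def _binary_topologies(n: int):
    """All rooted binary topologies over leaf slots 0..n-1, as nested tuples."""

    def insert(tree, x):
        yield (tree, x)
        if isinstance(tree, tuple):
            left, right = tree
            for sub in insert(left, x):
                yield (sub, right)
            for sub in insert(right, x):
                yield (left, sub)

    tops = [0]
    for x in range(1, n):
        tops = [t for base in tops for t in insert(base, x)]
    return tops


def _topology_cost(
    topo,
    slot_images: Sequence[dendropy.Node],
    index: _SpeciesIndex,
    dup_cost: float,
    loss_cost: float,
):
    """(image, score) of a candidate resolution; leaf slots contribute 0."""

    def rec(t):
        if not isinstance(t, tuple):
            return slot_images[t], 0.0
        (ml, sl), (mr, sr) = rec(t[0]), rec(t[1])
        m = index.lca(ml, mr)
        is_dup = m is ml or m is mr
        score = sl + sr + (dup_cost if is_dup else 0.0)
        for mc in (ml, mr):
            losses = index.depth[id(mc)] - index.depth[id(m)] - (0 if is_dup else 1)
            score += loss_cost * losses
        return m, score

    return rec(topo)


def _contract_weak_edges(tree: dendropy.Tree, threshold: float) -> None:
    """Collapse internal edges whose child support is below ``threshold``."""
    for node in list(tree.postorder_internal_node_iter()):
        if node is tree.seed_node:
            continue
        support = node_support(node)
        if support is not None and support < threshold:
            parent = node.parent_node
            for ch in list(node.child_nodes()):
                node.remove_child(ch)
                parent.add_child(ch)
            parent.remove_child(node)


def _subtree_newick(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    parts = sorted(_subtree_newick(ch) for ch in node.child_nodes())
    return "(" + ",".join(parts) + ")"


def _attach_topology(parent_of_slots: dendropy.Node, topo, slots: list[dendropy.Node]):
    """Rebuild a polytomy node's children according to a binary topology."""

    def build(t) -> dendropy.Node:
        if not isinstance(t, tuple):
            return slots[t]
        node = dendropy.Node()
        node.add_child(build(t[0]))
        node.add_child(build(t[1]))
        return node

    for ch in list(parent_of_slots.child_nodes()):
        parent_of_slots.remove_child(ch)
    top = build(topo)
    # graft the resolved top's two children directly under the polytomy node
    for ch in list(top.child_nodes()):
        top.remove_child(ch)
        parent_of_slots.add_child(ch)


# ---------------------------------------------------------------------------
# Reconciliation proper

def _reconcile_binary(
    gene_tree: dendropy.Tree,
    index: _SpeciesIndex,
    to_taxon: Callable[[str], str],
) -> ReconciliationResult:
    images = lca_map(gene_tree, index.tree, to_taxon)

    # deterministic internal labels by postorder
    i = 0
    for node in gene_tree.postorder_internal_node_iter():
        i += 1
        node.label = f"g{i}"

    event: dict[dendropy.Node, str] = {}
    event_map: dict[str, str] = {}
    n_dup = 0
    for node in gene_tree.postorder_internal_node_iter():
        children = node.child_nodes()
        is_dup = any(images[node] is images[ch] for ch in children)
        event[node] = "duplication" if is_dup else "speciation"
        event_map[node.label] = event[node]
        n_dup += int(is_dup)

    n_losses = 0
    loss_branches: dict[str, int] = {}
    branch_copies: dict[str, int] = {
        index.label[id(n)]: 0 for n in index.tree.preorder_node_iter()
    }

    def cover(top_excl_or_incl: list[dendropy.Node], child_is_dup: bool):
        nodes = top_excl_or_incl
        if child_is_dup and nodes:
            nodes = nodes[:-1]  # the edge ends mid-branch; child edges cover it
        for X in nodes:
            branch_copies[index.label[id(X)]] += 1

    # virtual stem edge above the gene root
    root = gene_tree.seed_node
    stem_path = index.path_down(index.tree.seed_node, images[root])
    cover(stem_path, not root.is_leaf() and event.get(root) == "duplication")

    for node in gene_tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        mp, mc = images[parent], images[node]
        p_dup = event[parent] == "duplication"
        path = index.path_down(mp, mc)
        covered = path if p_dup else path[1:]
        losses = index.depth[id(mc)] - index.depth[id(mp)] - (0 if p_dup else 1)
        if losses < 0:
            raise SeptevoError("negative loss count: invalid reconciliation state")
        n_losses += losses
        if losses:
            # the lineage passes silently through `losses` speciation nodes;
            # at each, the copy on the off-path sibling branch was lost
            through = path[:-1] if p_dup else path[1:-1]
            for X in through:
                for sib in X.child_nodes():
                    if sib not in path:
                        key = index.label[id(sib)]
                        loss_branches[key] = loss_branches.get(key, 0) + 1
        cover(covered, not node.is_leaf() and event[node] == "duplication")

    return ReconciliationResult(
        event_map=event_map,
        n_duplications=n_dup,
        n_losses=n_losses,
        branch_copies=branch_copies,
        n_optima=1,
        gene_tree_newick=_subtree_newick(gene_tree.seed_node),
        loss_branches=loss_branches,
    )


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_to_taxon: Union[None, Mapping[str, str], Callable[[str], str]] = None,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    dup_cost: float = 1.0,
    loss_cost: float = 1.0,
    polytomy_cap: int = DEFAULT_POLYTOMY_CAP,
    co_optimal_cap: int = DEFAULT_CO_OPTIMAL_CAP,
) -> list[ReconciliationResult]:
    """Duplication/loss reconciliation with support-based rearrangement.

    Gene-tree edges whose child support falls below ``support_threshold``
    are contracted; each polytomy is resolved exhaustively to minimize
    dup_cost * duplications + loss_cost * losses (resolutions decompose
    independently per polytomy because every polytomy root keeps its LCA
    image under any resolution).  All co-optimal reconciliations are
    returned, up to ``co_optimal_cap``, in deterministic order.
    """
    if not (0.0 <= support_threshold <= 1.0):
        raise InvalidInputError("support_threshold must lie in [0, 1]")
    index = _SpeciesIndex(species_tree)
    to_taxon = _resolve_leaf_to_taxon(leaf_to_taxon)

    work = gene_tree.clone(depth=1)
    _contract_weak_edges(work, support_threshold)
    images = lca_map(work, species_tree, to_taxon)
    polytomies = [
        n for n in work.postorder_internal_node_iter() if len(n.child_nodes()) > 2
    ]
    per_polytomy: list[tuple[dendropy.Node, list]] = []
    for poly in polytomies:
        k = len(poly.child_nodes())
        if k > polytomy_cap:
            raise UnresolvedPolytomyError(poly.label or _subtree_newick(poly), k, polytomy_cap)
        slots = list(poly.child_nodes())
        slot_images = [images[s] for s in slots]
        scored = []
        for topo in _binary_topologies(k):
            _, score = _topology_cost(topo, slot_images, index, dup_cost, loss_cost)
            scored.append((score, topo))
        best = min(s for s, _ in scored)
        optimal = [t for s, t in scored if abs(s - best) < 1e-9]
        optimal.sort(key=lambda t: _topo_sort_key(t, slots))
        per_polytomy.append((poly, optimal))

    n_optima = 1
    for _, optimal in per_polytomy:
        n_optima *= len(optimal)

    results: list[ReconciliationResult] = []
    choice_lists = [optimal for _, optimal in per_polytomy]
    for combo in itertools.product(*choice_lists):
        resolved = work.clone(depth=1)
        # clone preserves traversal order: align polytomy nodes by position
        orig_nodes = list(work.postorder_node_iter())
        new_nodes = list(resolved.postorder_node_iter())
        node_of = {id(o): n for o, n in zip(orig_nodes, new_nodes)}
        for (poly, _), topo in zip(per_polytomy, combo):
            poly_new = node_of[id(poly)]
            slots = list(poly_new.child_nodes())
            _attach_topology(poly_new, topo, slots)
        result = _reconcile_binary(resolved, index, to_taxon)
        result.n_optima = n_optima
        results.append(result)
        if len(results) >= co_optimal_cap:
            break
    results.sort(key=lambda r: r.gene_tree_newick)
    for r in results:
        r.n_optima = n_optima
    return results


def _topo_sort_key(topo, slots: list[dendropy.Node]):
    def rec(t) -> str:
        if not isinstance(t, tuple):
            return _subtree_newick(slots[t])
        a, b = sorted((rec(t[0]), rec(t[1])))
        return f"({a},{b})"

    return rec(topo)


def copy_number_profile(results: Sequence[ReconciliationResult]) -> dict[str, float]:
    """Per-species-branch mean gene copy number over co-optimal resolutions."""
    if not results:
        raise InvalidInputError("copy_number_profile requires at least one result")
    branches = results[0].branch_copies.keys()
    for r in results[1:]:
        if r.branch_copies.keys() != branches:
            raise InvalidInputError("results cover different species trees")
    return {
        b: sum(r.branch_copies[b] for r in results) / len(results) for b in branches
    }
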