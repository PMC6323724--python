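import itertools

import numpy as np
import pytest

from conftest import random_rooted_tree
from septevo.errors import InvalidInputError, MappingError, UnresolvedPolytomyError
from septevo.reconcile import (
    assign_groups,
    copy_number_profile,
    lca_map,
    reconcile,
)
from septevo.simulate import simulate_gene_family
from septevo.trees import read_newick


# ---------------------------------------------------------------------------
# Brute-force duplication/loss oracle: enumerate every valid map from gene
# internal nodes to species nodes and take the minimum dup+loss score.

def brute_force_min_cost(gene_tree, species_tree, leaf_to_taxon=None):
    leaf_to_taxon = leaf_to_taxon or (lambda lbl: lbl.split("|")[0])
    sp_nodes = list(species_tree.preorder_node_iter())
    depth, parent = {}, {}
    for node in sp_nodes:
        parent[id(node)] = node.parent_node
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1
    sp_leaf = {n.taxon.label: n for n in species_tree.leaf_node_iter()}

    def is_anc(a, b):  # a ancestor-or-equal of b
        while b is not None:
            if a is b:
                return True
            b = parent[id(b)]
        return False

    gene_nodes = list(gene_tree.postorder_node_iter())
    internal = [n for n in gene_nodes if not n.is_leaf()]
    fixed = {
        id(n): sp_leaf[leaf_to_taxon(n.taxon.label)] for n in gene_nodes if n.is_leaf()
    }
    # any valid image of an internal node must dominate every leaf image in
    # its subtree, so its candidates are the ancestors of the subtree LCA
    sub_lca = dict(fixed)
    for n in internal:
        img = None
        for c in n.child_nodes():
            ci = sub_lca[id(c)]
            if img is None:
                img = ci
            else:
                a, b = img, ci
                while not is_anc(a, b):
                    a = parent[id(a)]
                img = a
        sub_lca[id(n)] = img
    candidates = []
    for n in internal:
        anc = []
        node = sub_lca[id(n)]
        while node is not None:
            anc.append(node)
            node = parent[id(node)]
        candidates.append(anc)
    best = np.inf
    for assignment in itertools.product(*candidates):
        M = dict(fixed)
        for node, sp in zip(internal, assignment):
            M[id(node)] = sp
        ok = all(
            all(is_anc(M[id(n)], M[id(c)]) for c in n.child_nodes()) for n in internal
        )
        if not ok:
            continue
        cost = 0
        for n in internal:
            c1, c2 = n.child_nodes()
            below_distinct = (
                M[id(n)] is not M[id(c1)]
                and M[id(n)] is not M[id(c2)]
                and not any(
                    is_anc(kid, M[id(c1)]) and is_anc(kid, M[id(c2)])
                    for kid in M[id(n)].child_nodes()
                )
            )
            is_dup = not below_distinct
            cost += int(is_dup)
            for c in (c1, c2):
                cost += depth[id(M[id(c)])] - depth[id(M[id(n)])] - (0 if is_dup else 1)
        best = min(best, cost)
    return best


class TestLcaMap:
    def test_congruent_tree_maps_isomorphically(self, species_tree_small):
        gene = read_newick("((A|1:1,B|1:1):1,C|1:2):0;")
        images = lca_map(gene, species_tree_small)
        labels = {
            (n.taxon.label if n.is_leaf() else "int"): img
            for n, img in images.items()
        }
        assert labels["A|1"].taxon.label == "A"

    def test_same_taxon_cherry_maps_to_leaf(self, species_tree_small):
        gene = read_newick("(A|1:1,A|2:1):0;")
        images = lca_map(gene, species_tree_small)
        root_img = images[gene.seed_node]
        assert root_img.is_leaf() and root_img.taxon.label == "A"

    def test_hand_computed_lca_images(self, species_tree_small):
        gene = read_newick("((A|1:1,B|1:1):1,(A|2:1,C|1:1):1):0;")
        images = lca_map(gene, species_tree_small)
        by_label = {}
        for node, img in images.items():
            key = node.taxon.label if node.is_leaf() else frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            by_label[key] = img.label or img.taxon.label
        assert by_label[frozenset({"A|1", "B|1"})] == "AB"
        assert by_label[frozenset({"A|2", "C|1"})] == "R"
        assert by_label[frozenset({"A|1", "B|1", "A|2", "C|1"})] == "R"

    def test_unknown_taxon_raises(self, species_tree_small):
        gene = read_newick("(A|1:1,Z|1:1);")
        with pytest.raises(MappingError):
            lca_map(gene, species_tree_small)


class TestReconcile:
    def test_congruent_family_has_no_events(self, species_tree_small):
        gene = read_newick("((A|1:1,B|1:1):1,C|1:2):0;")
        results = reconcile(gene, species_tree_small)
        assert len(results) == 1
        r = results[0]
        assert (r.n_duplications, r.n_losses) == (0, 0)
        assert set(r.branch_copies.values()) == {1}
        assert r.n_optima == 1

    def test_worked_example_one_dup_two_losses(self, species_tree_small):
        gene = read_newick("((A|1:1,B|1:1):1,(A|2:1,C|1:1):1):0;")
        r = reconcile(gene, species_tree_small)[0]
        assert (r.n_duplications, r.n_losses) == (1, 2)
        assert r.branch_copies["R"] >= 1

    @pytest.mark.parametrize("n_gene,n_species,seed", [
        (4, 3, 0), (5, 4, 1), (6, 4, 2), (6, 5, 3), (7, 5, 4), (8, 5, 5),
        (8, 6, 6), (7, 6, 7), (5, 3, 8), (8, 4, 9),
    ])
    def test_matches_exhaustive_minimum(self, n_gene, n_species, seed):
        rng = np.random.default_rng(seed)
        species = random_rooted_tree([f"S{i}" for i in range(n_species)], rng)
        i = 0
        for n in species.postorder_internal_node_iter():
            i += 1
            n.label = f"n{i}"
        taxa = [f"S{int(rng.integers(n_species))}" for _ in range(n_gene)]
        labels = [f"{t}|{k}" for k, t in enumerate(taxa)]
        gene = random_rooted_tree(labels, rng)
        r = reconcile(gene, species)[0]
        assert r.n_duplications + r.n_losses == brute_force_min_cost(gene, species)

    def test_low_support_rearrangement_reduces_events(self, species_tree_small):
        # the wrong attachment of A|2 has weak support; collapsing and
        # re-resolving recovers the congruent, event-free history
        gene = read_newick("((A|1:1,C|1:1)0.5:1,B|1:1):0;")
        naive = reconcile(gene, species_tree_small, support_threshold=0.0)[0]
        rearranged = reconcile(gene, species_tree_small, support_threshold=0.9)
        best = rearranged[0]
        assert naive.n_duplications + naive.n_losses > 0
        assert best.n_duplications + best.n_losses == 0

    def test_co_optimal_resolutions_all_reported(self, species_tree_small):
        # a four-way polytomy of two A copies and two B copies admits
        # several equally parsimonious resolutions
        gene = read_newick("((A|1:1,A|2:1,B|1:1,B|2:1)0.5:1,C|1:1):0;")
        results = reconcile(gene, species_tree_small)
        assert len(results) >= 2
        scores = {r.n_duplications + r.n_losses for r in results}
        assert len(scores) == 1
        assert all(r.n_optima == len(results) for r in results)

    def test_polytomy_cap_raises(self, species_tree_small):
        leaves = ",".join(f"A|{i}:1" for i in range(9))
        gene = read_newick(f"(({leaves})0.1:1,C|1:1):0;")
        with pytest.raises(UnresolvedPolytomyError):
            reconcile(gene, species_tree_small, polytomy_cap=7)

    def test_leaf_order_permutation_invariant(self, species_tree_small):
        a = read_newick("((A|1:1,B|1:1):1,(A|2:1,C|1:1):1):0;")
        b = read_newick("((C|1:1,A|2:1):1,(B|1:1,A|1:1):1):0;")
        ra, rb = reconcile(a, species_tree_small)[0], reconcile(b, species_tree_small)[0]
        assert (ra.n_duplications, ra.n_losses) == (rb.n_duplications, rb.n_losses)

    def test_roundtrip_recovers_true_duplications(self, species_tree_22):
        for seed in (3, 5, 8):
            gene, truth = simulate_gene_family(species_tree_22, 8e-4, 0.0, seed=seed)
            true_dups = sum(
                1 for kind, _ in truth.true_events.values() if kind == "duplication"
            )
            r = reconcile(gene, species_tree_22)[0]
            assert r.n_duplications == true_dups
            assert r.n_losses == 0


class TestCopyNumberProfile:
    def test_single_result_passthrough(self, species_tree_small):
        gene = read_newick("((A|1:1,B|1:1):1,C|1:2):0;")
        results = reconcile(gene, species_tree_small)
        profile = copy_number_profile(results)
        assert profile == {k: float(v) for k, v in results[0].branch_copies.items()}

    def test_mean_over_two_results(self, species_tree_small):
        gene = read_newick("((A|1:1,A|2:1,B|1:1,B|2:1)0.5:1,C|1:1):0;")
        results = reconcile(gene, species_tree_small)
        profile = copy_number_profile(results)
        manual = {
            b: sum(r.branch_copies[b] for r in results) / len(results)
            for b in results[0].branch_copies
        }
        assert profile == manual

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            copy_number_profile([])


class TestAssignGroups:
    def test_worked_anchor_example(self):
        tree = read_newick("(((x:1,AspB:1):1,y:1):1,AspD:1);")
        got = assign_groups(tree, {"AspB": "2A", "AspD": "1A"})
        assert got == {"x": "2A", "y": "2A", "AspB": "2A", "AspD": "1A"}

    def test_anchor_cherry_each_own_group(self):
        tree = read_newick("(AspB:1,AspD:1);")
        got = assign_groups(tree, {"AspB": "2A", "AspD": "1A"})
        assert got == {"AspB": "2A", "AspD": "1A"}

    def test_leaf_outside_all_anchored_clades_unclassified(self):
        tree = read_newick("((AspB:1,x:1):1,(AspD:1,(AspA:1,z:1):1):1);")
        got = assign_groups(tree, {"AspB": "2A", "AspD": "1A", "AspA": "3"})
        assert got["x"] == "2A"
        assert got["z"] == "3"
        # AspD's maximal clean clade is itself: its parent contains AspA
        assert got["AspD"] == "1A"

    def test_missing_anchor_rejected(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(InvalidInputError):
            assign_groups(tree, {"Z": "1A"})
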