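"""Seeded synthetic-data generators for every stage of the analysis.

The generators emulate the statistical structure of an opisthokont septin
study: an ultrametric species tree of ~22 taxa (root age 1350 Myr), gene
families evolving along it by duplication and loss, binary presence/absence
characters evolving under a two-state Markov chain, septin-like proteins
carrying G-box motifs among decoys, and toy two-chain dimer structures with
planted interface contacts across 17 taxa and 5 crystal-template types.
Each generator records ground truth so downstream inference can be scored,
and every random draw flows from a single seeded generator per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .ancestral import CharacterMatrix, transition_matrix
from .contacts import TEMPLATE_LABELS, Atom, Residue, Structure
from .errors import EmptyFamilyError, InvalidParameterError
from .identify import ProteinRecord

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_species_tree",
    "simulate_gene_family",
    "simulate_binary_characters",
    "simulate_septin_proteome",
    "simulate_dimer_structures",
]

#: Default planted interface positions (reference coordinates), mirroring the
#: study design of 29 G-interface and 20 NC-interface consensus residues.
DEFAULT_G_POSITIONS = (
    31, 32, 33, 55, 56, 78, 79, 80, 101, 102, 120, 121, 140, 141, 142,
    160, 161, 180, 181, 200, 201, 220, 221, 240, 241, 255, 256, 270, 271,
)
DEFAULT_NC_POSITIONS = (
    12, 13, 45, 46, 68, 69, 90, 91, 110, 111,
    150, 151, 170, 171, 210, 211, 230, 231, 260, 261,
)

#: Sequence background alphabet for the proteome generator: the 20 amino
#: acids minus D and K, so no G-box pattern can arise outside planted motifs.
_BACKGROUND_ALPHABET = "ACEFGHILMNPQRSTVWY"

_G1_MOTIF = "GQSGLGKS"   # matches [AG]x{4}GK[ST]
_G3_MOTIF = "DTPG"       # matches Dx{2}G
_G4_MOTIF = "TKLD"       # matches [NT]KxD

SEPTIN_DOMAIN_CHOICES = ("P-Loop_NTPase", "CDC3", "CDC_septin")
CONFLICT_DOMAIN_CHOICES = ("LysM", "DNA_binding")


@dataclass
class SimulationConfig:
    """Study-design parameters for all generators.

    Rates are per lineage per Myr on a tree whose root age defaults to
    1350 Myr (the constrained age of the opisthokont ancestor).
    """

    n_taxa: int = 22
    birth_rate: float = 0.01
    root_age: float = 1350.0
    dup_rate: float = 5e-4
    loss_rate: float = 5e-4
    q01: float = 2e-4
    q10: float = 2e-4
    n_chars: int = 7
    n_groups: int = 7
    seq_length: int = 300
    planted_G_positions: tuple[int, ...] = DEFAULT_G_POSITIONS
    planted_NC_positions: tuple[int, ...] = DEFAULT_NC_POSITIONS
    contact_distance: float = 3.8
    n_structure_taxa: int = 17
    #: (interface, position) -> number of taxa whose planted contact is removed
    contact_dropout: Mapping[tuple[str, int], int] = field(default_factory=dict)
    n_true_septins: int = 15
    n_borderline: int = 5
    n_decoys: int = 70
    n_conflicting: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise InvalidParameterError("n_taxa must be >= 2")
        for name in ("birth_rate", "dup_rate", "loss_rate", "q01", "q10"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.birth_rate <= 0:
            raise InvalidParameterError("birth_rate must be positive")
        if self.seq_length < 250:
            raise InvalidParameterError("seq_length must be >= 250")
        if set(self.planted_G_positions) & set(self.planted_NC_positions):
            raise InvalidParameterError("planted G and NC positions must be disjoint")
        for pos in (*self.planted_G_positions, *self.planted_NC_positions):
            if not 1 <= pos <= self.seq_length:
                raise InvalidParameterError(
                    f"planted position {pos} outside 1..{self.seq_length}"
                )


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each synthetic dataset."""

    true_events: dict[str, tuple[str, str]] = field(default_factory=dict)
    # gene node label -> (event kind, species branch label)
    true_losses: list[str] = field(default_factory=list)  # species branch labels
    true_states: dict[str, list[int]] = field(default_factory=dict)
    # species node label -> state per character
    true_interface: set[tuple[str, int]] = field(default_factory=set)
    true_septin_ids: list[str] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "true_events": {k: list(v) for k, v in self.true_events.items()},
            "true_losses": self.true_losses,
            "true_states": self.true_states,
            "true_interface": sorted([list(x) for x in self.true_interface]),
            "true_septin_ids": self.true_septin_ids,
            "categories": self.categories,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Species tree

def simulate_species_tree(
    n_taxa: int,
    birth_rate: float,
    seed: int,
    root_age: float = 1350.0,
) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric species tree scaled to ``root_age``.

    Leaves are named T01..Tnn and internal nodes N1.. (root first, preorder).
    """
    if n_taxa < 2:
        raise InvalidParameterError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise InvalidParameterError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    times = {id(root): 0.0}
    tips = [root.new_child(), root.new_child()]
    t = 0.0
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        parent = tips.pop(int(rng.integers(len(tips))))
        times[id(parent)] = t
        tips.append(parent.new_child())
        tips.append(parent.new_child())
    present = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        times[id(tip)] = present

    scale = root_age / present if present > 0 else 1.0
    leaf_i = internal_i = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (times[id(node)] - times[id(node.parent_node)]) * scale
        if node.is_leaf():
            leaf_i += 1
            node.taxon = taxa.new_taxon(f"T{leaf_i:02d}")
        else:
            internal_i += 1
            node.label = f"N{internal_i}"
    return tree


# ---------------------------------------------------------------------------
# Gene family birth-death

class _GNode:
    __slots__ = ("children", "length", "kind", "species", "label", "taxon")

    def __init__(self, kind: str, species: str, length: float = 0.0):
        self.children: list[_GNode] = []
        self.length = length
        self.kind = kind  # speciation | duplication | leaf
        self.species = species
        self.label: Optional[str] = None
        self.taxon: Optional[str] = None


def _species_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def simulate_gene_family(
    species_tree: dendropy.Tree,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    stem_length: float = 0.0,
) -> tuple[dendropy.Tree, TruthRecord]:
    """Gene family evolving by duplication and loss along the species tree.

    A linear birth-death process runs along every species branch; at each
    species node, every surviving gene lineage bifurcates into both
    descendant branches.  Speciation nodes with one fully lost side are
    suppressed.  Raises :class:`EmptyFamilyError` when no copy survives.
    Gene leaves are labelled ``taxon|copy``; surviving internal nodes carry
    labels g1.. (postorder) recorded in the truth with their species branch.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise InvalidParameterError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    truth = TruthRecord()
    total = dup_rate + loss_rate

    def evolve(species_node: dendropy.Node, remaining: float, consumed: float):
        """Evolve one lineage entering `species_node`'s branch with `remaining`
        time to the node; returns a _GNode or None if the lineage dies."""
        label = _species_label(species_node)
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if wait >= remaining:
                break
            remaining -= wait
            consumed += wait
            if rng.random() < (dup_rate / total if total else 0.0):
                left = evolve(species_node, remaining, 0.0)
                right = evolve(species_node, remaining, 0.0)
                if left is None and right is None:
                    return None
                if left is None or right is None:
                    survivor = left if right is None else right
                    survivor.length += consumed
                    return survivor
                node = _GNode("duplication", label, consumed)
                node.children = [left, right]
                return node
            truth.true_losses.append(label)
            return None
        # reached the species node
        if species_node.is_leaf():
            node = _GNode("leaf", label, remaining + consumed)
            node.taxon = label
            return node
        kids = [
            evolve(ch, ch.edge.length or 0.0, 0.0) for ch in species_node.child_nodes()
        ]
        alive = [k for k in kids if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            alive[0].length += remaining + consumed
            return alive[0]
        node = _GNode("speciation", label, remaining + consumed)
        node.children = alive
        return node

    root = evolve(species_tree.seed_node, stem_length, 0.0)
    if root is None:
        raise EmptyFamilyError("all gene copies were lost")

    # name leaves per taxon in deterministic order, internals postorder
    copy_counter: dict[str, int] = {}
    internal_i = 0

    def name(node: _GNode):
        nonlocal internal_i
        for ch in node.children:
            name(ch)
        if node.kind == "leaf":
            copy_counter[node.taxon] = copy_counter.get(node.taxon, 0) + 1
            node.label = f"{node.taxon}|{copy_counter[node.taxon]}"
        else:
            internal_i += 1
            node.label = f"g{internal_i}"
            truth.true_events[node.label] = (node.kind, node.species)

    name(root)

    taxa = dendropy.TaxonNamespace()
    gene_tree = dendropy.Tree(taxon_namespace=taxa)

    def build(gnode: _GNode, dnode: dendropy.Node):
        dnode.edge.length = gnode.length
        if gnode.kind == "leaf":
            dnode.taxon = taxa.new_taxon(gnode.label)
        else:
            dnode.label = gnode.label
            for ch in gnode.children:
                build(ch, dnode.new_child())

    build(root, gene_tree.seed_node)
    return gene_tree, truth


# ---------------------------------------------------------------------------
# Binary characters

def simulate_binary_characters(
    tree: dendropy.Tree,
    q01: float,
    q10: float,
    n_chars: int,
    seed: int,
) -> tuple[CharacterMatrix, TruthRecord]:
    """Binary characters evolving under the two-state chain along ``tree``.

    The root state is drawn from the stationary distribution
    (q10, q01)/(q01+q10), or uniformly when both rates are zero.  True
    states at every node are recorded per character.
    """
    if q01 < 0 or q10 < 0:
        raise InvalidParameterError("rates must be non-negative")
    if n_chars < 1:
        raise InvalidParameterError("n_chars must be >= 1")
    rng = np.random.default_rng(seed)
    truth = TruthRecord()
    r = q01 + q10
    p1_root = 0.5 if r == 0 else q01 / r

    states: dict[int, np.ndarray] = {}
    leaf_rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            s = (rng.random(n_chars) < p1_root).astype(int)
        else:
            parent = states[id(node.parent_node)]
            P = transition_matrix(q01, q10, node.edge.length or 0.0)
            flip_from0 = rng.random(n_chars) < P[0, 1]
            flip_from1 = rng.random(n_chars) < P[1, 1]
            s = np.where(parent == 0, flip_from0, flip_from1).astype(int)
        states[id(node)] = s
        label = _species_label(node)
        truth.true_states[label] = [int(x) for x in s]
        if node.is_leaf():
            leaf_rows[label] = s

    data = pd.DataFrame(
        {f"C{j + 1}": [leaf_rows[t][j] for t in sorted(leaf_rows)] for j in range(n_chars)},
        index=pd.Index(sorted(leaf_rows), name="taxon"),
    )
    return CharacterMatrix(data), truth


# ---------------------------------------------------------------------------
# Proteome with planted septins and decoys

def _random_background(rng: np.random.Generator, length: int) -> list[str]:
    alphabet = np.array(list(_BACKGROUND_ALPHABET))
    return list(alphabet[rng.integers(len(alphabet), size=length)])


def _plant(seq: list[str], motif: str, start0: int) -> None:
    seq[start0 : start0 + len(motif)] = list(motif)


def simulate_septin_proteome(
    config: SimulationConfig, seed: int
) -> tuple[list[ProteinRecord], TruthRecord]:
    """Proteome of genuine septins, borderline septins and decoys.

    Categories: (a) all three G boxes plus a septin domain label;
    (b) exactly two G boxes, no domain label; (c) decoys with at most one
    box; (d) decoys with two boxes plus a conflicting domain label.
    Backgrounds are drawn from a reduced alphabet so no box can arise by
    chance; truth lists the category of every protein and the ids of the
    planted septins (a + b).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    truth = TruthRecord()
    taxa = [f"T{i + 1:02d}" for i in range(config.n_taxa)]
    records: list[ProteinRecord] = []
    counter = 0

    def emit(category: str, domains: tuple[str, ...], motifs: Sequence[tuple[str, int]]):
        nonlocal counter
        counter += 1
        pid = f"P{counter:04d}"
        taxon = taxa[(counter - 1) % len(taxa)]
        seq = _random_background(rng, config.seq_length)
        for motif, start0 in motifs:
            _plant(seq, motif, start0)
        label_set = frozenset(domains)
        records.append(ProteinRecord(pid, taxon, "".join(seq), label_set))
        truth.categories[pid] = category
        if category in ("septin", "borderline"):
            truth.true_septin_ids.append(pid)

    g1, g3, g4 = (_G1_MOTIF, 20), (_G3_MOTIF, 100), (_G4_MOTIF, 180)
    for _ in range(config.n_true_septins):
        domain = SEPTIN_DOMAIN_CHOICES[int(rng.integers(len(SEPTIN_DOMAIN_CHOICES)))]
        emit("septin", (domain,), [g1, g3, g4])
    for _ in range(config.n_borderline):
        emit("borderline", (), [g1, g3])
    for i in range(config.n_decoys):
        motifs = [g3] if i % 2 == 0 else []  # at most one box
        emit("decoy", (), motifs)
    for _ in range(config.n_conflicting):
        domain = CONFLICT_DOMAIN_CHOICES[int(rng.integers(len(CONFLICT_DOMAIN_CHOICES)))]
        emit("conflicting", (domain,), [g1, g3])
    return records, truth


def write_proteome(
    records: Sequence[ProteinRecord],
    truth: TruthRecord,
    fasta_path: str,
    annotations_path: str,
    groups: Optional[Mapping[str, str]] = None,
) -> None:
    """FASTA plus annotation TSV (protein_id, taxon, domain_labels, category,
    group); ``groups`` optionally assigns paralog-Group labels."""
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")
    with open(annotations_path, "w") as fh:
        fh.write("protein_id\ttaxon\tdomain_labels\tcategory\tgroup\n")
        for r in records:
            cat = truth.categories.get(r.id, "")
            grp = (groups or {}).get(r.id, "")
            fh.write(f"{r.id}\t{r.taxon}\t{','.join(sorted(r.domain_labels))}\t{cat}\t{grp}\n")


# ---------------------------------------------------------------------------
# Dimer structures with planted interface contacts

_CHAIN_SPACING = 5.0     # A between consecutive residues along a chain
_CHAIN_SEPARATION = 10.0  # A between non-interacting chains
_JITTER = 0.05           # A of uniform coordinate noise


def simulate_dimer_structures(
    config: SimulationConfig, seed: int
) -> tuple[list[Structure], TruthRecord]:
    """Two-chain pseudo-atom structures with planted interface contacts.

    For each of ``n_structure_taxa`` taxa and each of the five template
    types, one carbon pseudo-atom per residue is laid out on two parallel
    chains ``_CHAIN_SEPARATION`` apart; residues planted for the template's
    interface type are brought to ``contact_distance`` across the chains.
    ``contact_dropout`` removes the planted contact of a position from a
    chosen number of taxa (deterministically, given the seed), which
    exercises the min-taxa consensus rule downstream.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    truth = TruthRecord()
    taxa = [f"T{i + 1:02d}" for i in range(config.n_structure_taxa)]
    planted = {
        "G": tuple(config.planted_G_positions),
        "NC": tuple(config.planted_NC_positions),
    }
    for interface, positions in planted.items():
        for pos in positions:
            truth.true_interface.add((interface, pos))

    dropped: dict[tuple[str, int], set[str]] = {}
    for (interface, pos), n_drop in sorted(config.contact_dropout.items()):
        if (interface, pos) not in truth.true_interface:
            raise InvalidParameterError(
                f"dropout refers to unplanted position ({interface}, {pos})"
            )
        if not 0 <= n_drop <= len(taxa):
            raise InvalidParameterError("dropout count outside 0..n_structure_taxa")
        chosen = rng.choice(len(taxa), size=n_drop, replace=False)
        dropped[(interface, pos)] = {taxa[int(i)] for i in chosen}

    structures: list[Structure] = []
    for taxon in taxa:
        for template in TEMPLATE_LABELS:
            interface = template.split(":")[0]
            contact_set = {
                pos
                for pos in planted[interface]
                if taxon not in dropped.get((interface, pos), set())
            }
            chains: dict[str, list[Residue]] = {"A": [], "B": []}
            for i in range(1, config.seq_length + 1):
                x = i * _CHAIN_SPACING
                jit = rng.uniform(-_JITTER, _JITTER, size=6)
                ya = 0.0
                yb = (
                    config.contact_distance if i in contact_set else _CHAIN_SEPARATION
                )
                for chain_id, (px, py, pz), j in (
                    ("A", (x, ya, 0.0), jit[:3]),
                    ("B", (x, yb, 0.0), jit[3:]),
                ):
                    jitter = j if yb == _CHAIN_SEPARATION or chain_id == "A" else j * 0.0
                    atom = Atom(
                        name="CA",
                        element="C",
                        x=px + jitter[0],
                        y=py + jitter[1],
                        z=pz + jitter[2],
                        radius=1.7,
                        is_backbone=True,
                    )
                    chains[chain_id].append(Residue(i, "ALA", (atom,)))
            structures.append(
                Structure(
                    id=f"{taxon}_{template.replace(':', '_')}",
                    taxon=taxon,
                    template=template,
                    chains=chains,
                )
            )
    return structures, truth
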