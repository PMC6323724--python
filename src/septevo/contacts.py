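"""Inter-chain residue contact detection and cross-taxon interface consensus.

Septin filaments are held together by two alternating surfaces: the G
interface (around the GTP pocket) and the NC interface (the amino/carboxy
face).  Given two-chain dimer structures modelled on different crystal
templates, atoms on opposite chains are called in contact when their
centres approach within the sum of their van der Waals radii plus a probe
diameter (default 0.5 A, boundary inclusive) — a deterministic surrogate
for probe-style dot-surface contact detection.  Pairs where both atoms are
peptide-backbone atoms closer than the sum of their radii are discarded as
modelling clashes.  Contacts are deduplicated to residues, mapped to a
reference residue numbering, and a position is called a consensus interface
residue when it contacts in at least ``min_taxa`` of ``n_taxa`` taxa in at
least one template of that interface type.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError, MappingError

__all__ = [
    "VDW_RADII",
    "BACKBONE_ATOMS",
    "TEMPLATE_LABELS",
    "Atom",
    "Residue",
    "Structure",
    "ContactRecord",
    "InterfaceConsensus",
    "detect_contacts",
    "residue_interface_set",
    "aggregate_interfaces",
    "group_frequency_profiles",
    "interface_cluster",
    "read_pdb",
    "write_pdb",
]

#: Standard van der Waals radii (A) by element; unknown elements fall back to carbon.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10, "P": 1.80,
}
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: The five crystal-template dimer types: interface type, chain group pairing.
TEMPLATE_LABELS = ("G:1-1", "G:2-2", "G:1-2", "NC:2-2", "NC:1-2")

DEFAULT_PROBE_DIAMETER = 0.5
DEFAULT_N_TAXA = 17
DEFAULT_MIN_TAXA = 10


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    radius: float
    is_backbone: bool

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise InvalidInputError(f"atom {self.name!r}: non-finite coordinates")
        if self.radius <= 0:
            raise InvalidInputError(f"atom {self.name!r}: non-positive radius")


@dataclass(frozen=True)
class Residue:
    number: int
    name: str
    atoms: tuple[Atom, ...]


@dataclass
class Structure:
    id: str
    taxon: str
    template: str
    chains: dict[str, list[Residue]]  # exactly two chains

    def __post_init__(self):
        if len(self.chains) != 2:
            raise InvalidInputError(
                f"structure {self.id!r}: expected exactly 2 chains, got {len(self.chains)}"
            )

    @property
    def interface_type(self) -> str:
        return self.template.split(":")[0]


@dataclass(frozen=True)
class ContactRecord:
    residue_a: tuple[str, int]  # (chain, residue number)
    residue_b: tuple[str, int]
    min_gap: float              # distance - r_i - r_j over the closest atom pair
    interface: str              # G | NC


@dataclass(frozen=True)
class InterfaceConsensus:
    position: int
    interface: str
    per_template: Mapping[str, int]
    max_count: int
    proportion: float
    consensus: bool


# ---------------------------------------------------------------------------
# Contact detection

def _chain_arrays(residues: Sequence[Residue]):
    coords, radii, backbone, res_nums = [], [], [], []
    for res in residues:
        for atom in res.atoms:
            coords.append((atom.x, atom.y, atom.z))
            radii.append(atom.radius)
            backbone.append(atom.is_backbone)
            res_nums.append(res.number)
    return (
        np.array(coords, dtype=float).reshape(-1, 3),
        np.array(radii),
        np.array(backbone, dtype=bool),
        np.array(res_nums),
    )


def detect_contacts(
    structure: Structure, probe_diameter: float = DEFAULT_PROBE_DIAMETER
) -> list[ContactRecord]:
    """All inter-chain residue contacts of a two-chain structure.

    An atom pair (one atom per chain) is in contact iff
    ``distance <= r_i + r_j + probe_diameter`` (inclusive).  Backbone-
    backbone pairs overlapping harder than their radii allow are treated as
    modelling clashes and discarded.  Atom pairs are collapsed to residue
    pairs, keeping the minimal gap ``distance - r_i - r_j``.
    """
    if probe_diameter < 0:
        raise InvalidParameterError("probe_diameter must be >= 0")
    (name_a, name_b) = sorted(structure.chains)
    xa, ra, ba, na = _chain_arrays(structure.chains[name_a])
    xb, rb, bb, nb = _chain_arrays(structure.chains[name_b])
    if len(xa) == 0 or len(xb) == 0:
        return []
    dist = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    vdw_sum = ra[:, None] + rb[None, :]
    contact = dist <= vdw_sum + probe_diameter
    clash = (ba[:, None] & bb[None, :]) & (dist < vdw_sum)
    keep = contact & ~clash

    best: dict[tuple[int, int], float] = {}
    ii, jj = np.nonzero(keep)
    gaps = dist[ii, jj] - vdw_sum[ii, jj]
    for i, j, gap in zip(ii, jj, gaps):
        key = (int(na[i]), int(nb[j]))
        if key not in best or gap < best[key]:
            best[key] = float(gap)
    return [
        ContactRecord(
            residue_a=(name_a, res_a),
            residue_b=(name_b, res_b),
            min_gap=gap,
            interface=structure.interface_type,
        )
        for (res_a, res_b), gap in sorted(best.items())
    ]


def residue_interface_set(contacts: Iterable[ContactRecord]) -> set[tuple[str, int]]:
    """Residues participating in any contact, deduplicated across atoms."""
    out: set[tuple[str, int]] = set()
    for c in contacts:
        out.add(c.residue_a)
        out.add(c.residue_b)
    return out


# ---------------------------------------------------------------------------
# Cross-taxon aggregation

def aggregate_interfaces(
    residue_sets: Mapping[tuple[str, str], Iterable[tuple[str, int]]],
    reference_maps: Optional[Mapping[str, Mapping[int, int]]] = None,
    n_taxa: int = DEFAULT_N_TAXA,
    min_taxa: int = DEFAULT_MIN_TAXA,
) -> list[InterfaceConsensus]:
    """Consensus interface positions across taxa and crystal templates.

    ``residue_sets`` maps (taxon, template_label) to the interacting
    residues of that structure.  ``reference_maps`` maps each taxon's own
    residue numbers to reference coordinates (identity when omitted);
    unmappable residues are dropped.  For each reference position and
    interface type, the interacting-taxon count is taken per template and
    the maximum over templates of that interface compared against
    ``min_taxa``.
    """
    if min_taxa < 0 or n_taxa <= 0:
        raise InvalidParameterError("need n_taxa > 0 and min_taxa >= 0")
    # (interface, position) -> template -> set of taxa
    counts: dict[tuple[str, int], dict[str, set[str]]] = {}
    templates_by_interface: dict[str, set[str]] = {}
    for (taxon, template), residues in residue_sets.items():
        interface = template.split(":")[0]
        templates_by_interface.setdefault(interface, set()).add(template)
        ref_map = None if reference_maps is None else reference_maps.get(taxon)
        for _, res_num in residues:
            if ref_map is None:
                pos = res_num
            elif res_num in ref_map:
                pos = ref_map[res_num]
            else:
                continue  # residue falls in a reference gap column; dropped
            slot = counts.setdefault((interface, pos), {})
            slot.setdefault(template, set()).add(taxon)

    out = []
    for (interface, pos), per_template_taxa in sorted(counts.items()):
        per_template = {
            t: len(per_template_taxa.get(t, set()))
            for t in sorted(templates_by_interface[interface])
        }
        max_count = max(per_template.values())
        out.append(
            InterfaceConsensus(
                position=pos,
                interface=interface,
                per_template=per_template,
                max_count=max_count,
                proportion=max_count / n_taxa,
                consensus=max_count >= min_taxa,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Logo matrices and interface clustering

def group_frequency_profiles(
    alignment,
    group_assignment: Mapping[str, str],
    positions: Iterable[int],
    reference_map,
    pseudocount: float = 0.0,
    max_bits: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Per-Group residue frequency matrices at reference positions.

    Suitable as direct sequence-logo input: rows are reference positions,
    columns the 20 amino acids plus ``gap`` and ``information`` (in bits,
    ``max_bits`` minus the Shannon entropy of the residue distribution).
    Empty Groups are skipped.
    """
    from .conservation import AMINO_ACIDS, _AA_INDEX

    positions = sorted(set(positions))
    groups = sorted(set(group_assignment.values()))
    members = {
        g: sorted(sid for sid, gg in group_assignment.items() if gg == g) for g in groups
    }
    out: dict[str, pd.DataFrame] = {}
    for group in groups:
        ids = [sid for sid in members[group] if sid in alignment.sequences]
        if not ids:
            continue
        rows = []
        for pos in positions:
            col = reference_map.residue_to_column.get(pos)
            if col is None:
                raise MappingError(f"reference position {pos} not in the alignment map")
            counts = np.full(20, float(pseudocount))
            n_gap = 0
            for sid in ids:
                ch = alignment.sequences[sid][col - 1]
                if ch in _AA_INDEX:
                    counts[_AA_INDEX[ch]] += 1.0
                else:
                    n_gap += 1
            total = counts.sum()
            freqs = counts / total if total > 0 else counts
            nz = freqs[freqs > 0]
            entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
            row = dict(zip(AMINO_ACIDS, freqs))
            row["gap"] = n_gap / len(ids)
            row["information"] = max_bits - entropy if total > 0 else 0.0
            rows.append(row)
        out[group] = pd.DataFrame(rows, index=pd.Index(positions, name="position"))
    return out


def interface_cluster(
    positions: Sequence[int], max_gap: int = 3
) -> list[tuple[int, int]]:
    """Group sorted consensus positions into contiguous interacting groups.

    Successive positions at most ``max_gap`` apart belong to one group;
    groups are returned as inclusive (start, end) intervals in order.
    """
    if max_gap < 0:
        raise InvalidParameterError("max_gap must be >= 0")
    pos = sorted(set(positions))
    if not pos:
        return []
    intervals = []
    start = prev = pos[0]
    for p in pos[1:]:
        if p - prev <= max_gap:
            prev = p
        else:
            intervals.append((start, prev))
            start = prev = p
    intervals.append((start, prev))
    return intervals


# ---------------------------------------------------------------------------
# Minimal PDB I/O (fixed-column ATOM records, first model, altloc ''/'A')

def write_pdb(structure: Structure, path: str) -> None:
    serial = 0
    with open(path, "w") as fh:
        for chain_id in sorted(structure.chains):
            for res in structure.chains[chain_id]:
                for atom in res.atoms:
                    serial += 1
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
                    fh.write(
                        f"ATOM  {serial:5d} {name}{'':1}{res.name:>3} "
                        f"{chain_id}{res.number:4d}{'':1}   "
                        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}\n"
                    )
            fh.write("TER\n")
        fh.write("END\n")


def read_pdb(
    path: str,
    structure_id: str = "",
    taxon: str = "",
    template: str = TEMPLATE_LABELS[0],
    vdw_radii: Mapping[str, float] = VDW_RADII,
) -> Structure:
    chains: dict[str, dict[int, tuple[str, list[Atom]]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break  # first model only
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21]
            res_num = int(line[22:26])
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            element = line[76:78].strip() or name[:1]
            atom = Atom(
                name=name,
                element=element,
                x=x,
                y=y,
                z=z,
                radius=vdw_radii.get(element, vdw_radii["C"]),
                is_backbone=name in BACKBONE_ATOMS,
            )
            res_slot = chains.setdefault(chain_id, {}).setdefault(res_num, (res_name, []))
            res_slot[1].append(atom)
    built = {
        cid: [
            Residue(num, res_name, tuple(atoms))
            for num, (res_name, atoms) in sorted(res_map.items())
        ]
        for cid, res_map in chains.items()
    }
    return Structure(
        id=structure_id or path, taxon=taxon, template=template, chains=built
    )


def write_consensus(consensus: Sequence[InterfaceConsensus], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ref_position", "interface", "max_count", "proportion", "consensus"])
        for c in consensus:
            w.writerow(
                [c.position, c.interface, c.max_count, f"{c.proportion:.4f}", int(c.consensus)]
            )
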