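"""Jensen-Shannon divergence conservation scoring of alignment columns.

Each column's amino-acid distribution is compared against a background
distribution with the Jensen-Shannon divergence (log base 2, lambda = 0.5),
down-weighted by the column's gap fraction — the scheme popularized by
Capra & Singh for ranking functionally important residues.  Scores lie in
[0, 1].  Columns are mapped onto the residue numbering of a chosen
reference sequence (here, a budding-yeast Cdc3-like septin) so that
conservation, interface contacts and sequence motifs share one coordinate
system.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "AMINO_ACIDS",
    "BLOSUM62_BACKGROUND",
    "Alignment",
    "ReferenceMap",
    "ConservationProfile",
    "column_distribution",
    "js_divergence",
    "conservation_profile",
    "map_to_reference",
    "motif_overlap",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"

#: Background amino-acid frequencies underlying the BLOSUM62 matrix
#: (normalized below); the standard background of the Capra-Singh scorer.
_B62 = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}
BLOSUM62_BACKGROUND = np.array([_B62[aa] for aa in AMINO_ACIDS])
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()

DEFAULT_PSEUDOCOUNT = 1e-7


class Alignment:
    """A multiple sequence alignment: id -> gapped sequence, equal lengths."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise InvalidInputError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise InvalidInputError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.length = lengths.pop()

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")})

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid}\n{seq}\n")

    def subset(self, exclude_ids: Iterable[str]) -> "Alignment":
        excluded = set(exclude_ids)
        kept = {k: v for k, v in self.sequences.items() if k not in excluded}
        if not kept:
            raise InvalidInputError("excluding those ids leaves an empty alignment")
        return Alignment(kept)


@dataclass
class ReferenceMap:
    """Bijection between alignment columns and reference residue numbers."""

    reference_id: str
    column_to_residue: dict[int, int]  # 1-based column -> 1-based residue
    residue_to_column: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.residue_to_column:
            self.residue_to_column = {r: c for c, r in self.column_to_residue.items()}
        if len(self.residue_to_column) != len(self.column_to_residue):
            raise InvalidInputError("reference map is not a bijection")


@dataclass
class ConservationProfile:
    scores: np.ndarray  # index 0 = column 1
    window: int
    gap_weighting: bool
    background: str

    def score(self, column: int) -> float:
        return float(self.scores[column - 1])


def column_distribution(
    alignment: Alignment, column: int, pseudocount: float = 0.0
) -> tuple[np.ndarray, float]:
    """Residue frequencies (over the 20 amino acids) and gap fraction."""
    if not 1 <= column <= alignment.length:
        raise InvalidParameterError(f"column {column} outside 1..{alignment.length}")
    counts = np.zeros(20)
    n_gap = 0
    n_total = 0
    for seq in alignment.sequences.values():
        ch = seq[column - 1]
        n_total += 1
        if ch in _AA_INDEX:
            counts[_AA_INDEX[ch]] += 1
        else:
            n_gap += 1  # gaps and ambiguous residues treated alike
    gap_fraction = n_gap / n_total
    counts = counts + pseudocount
    total = counts.sum()
    if total == 0.0:
        return counts, gap_fraction  # all-gap column: zero vector signals it
    return counts / total, gap_fraction


def js_divergence(p: np.ndarray, q: np.ndarray, lam: float = 0.5) -> float:
    """Jensen-Shannon divergence in bits; symmetric at lambda = 0.5."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (0.0 < lam < 1.0):
        raise InvalidParameterError("lambda must lie in (0, 1)")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6 or np.any(v < 0):
            raise InvalidInputError(f"{name} is not a probability distribution")
    m = lam * p + (1.0 - lam) * q

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return lam * kl(p, m) + (1.0 - lam) * kl(q, m)


def _background_vector(background: str) -> np.ndarray:
    if background == "uniform":
        return np.full(20, 1.0 / 20.0)
    if background in ("blosum62", "blosum62-marginal"):
        return BLOSUM62_BACKGROUND
    raise InvalidParameterError(f"unknown background {background!r}")


def conservation_profile(
    alignment: Alignment,
    background: str = "blosum62",
    window: int = 0,
    exclude_ids: Iterable[str] = (),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lam: float = 0.5,
) -> ConservationProfile:
    """Per-column conservation: (1 - gap_fraction) * JSD(column, background).

    ``window > 0`` applies Capra-Singh flank averaging: the column keeps
    weight 0.5 and the flanking +-window columns share the other 0.5.
    """
    aln = alignment.subset(exclude_ids) if exclude_ids else alignment
    if window < 0 or window >= aln.length:
        raise InvalidParameterError("window must be >= 0 and smaller than the alignment")
    bg = _background_vector(background)
    raw = np.zeros(aln.length)
    for col in range(1, aln.length + 1):
        freqs, gap_fraction = column_distribution(aln, col, pseudocount)
        if freqs.sum() == 0.0:
            raw[col - 1] = 0.0
            continue
        raw[col - 1] = (1.0 - gap_fraction) * js_divergence(freqs, bg, lam)
    if window == 0:
        smoothed = raw
    else:
        smoothed = np.zeros_like(raw)
        for i in range(len(raw)):
            lo, hi = max(0, i - window), min(len(raw), i + window + 1)
            flanks = [raw[j] for j in range(lo, hi) if j != i]
            smoothed[i] = 0.5 * raw[i] + (0.5 * np.mean(flanks) if flanks else 0.5 * raw[i])
    return ConservationProfile(
        scores=smoothed, window=window, gap_weighting=True, background=background
    )


def map_to_reference(alignment: Alignment, reference_id: str) -> ReferenceMap:
    """Map alignment columns to reference residue numbers (ungapped positions)."""
    if reference_id not in alignment.sequences:
        raise InvalidInputError(f"reference {reference_id!r} not in alignment")
    seq = alignment.sequences[reference_id]
    column_to_residue: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(seq, start=1):
        if ch != GAP:
            residue += 1
            column_to_residue[col] = residue
    return ReferenceMap(reference_id, column_to_residue)


def motif_overlap(
    positions: Iterable[int],
    region_table: Mapping[str, tuple[int, int]],
) -> tuple[int, int, dict[str, int]]:
    """Count reference positions inside vs outside named regions.

    Regions are inclusive intervals in reference coordinates; a position in
    several regions still counts once as inside.
    """
    for name, (start, end) in region_table.items():
        if start > end:
            raise InvalidInputError(f"region {name!r}: start {start} > end {end}")
    inside = outside = 0
    per_region = {name: 0 for name in region_table}
    for pos in positions:
        hit = False
        for name, (start, end) in region_table.items():
            if start <= pos <= end:
                per_region[name] += 1
                hit = True
        if hit:
            inside += 1
        else:
            outside += 1
    return inside, outside, per_region


def write_profile(
    profile: ConservationProfile,
    ref_map: Optional[ReferenceMap],
    path: str,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["column", "ref_position", "score"])
        for col in range(1, len(profile.scores) + 1):
            ref = ref_map.column_to_residue.get(col, "") if ref_map else ""
            w.writerow([col, ref, f"{profile.scores[col - 1]:.6f}"])
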