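"""Septin candidate identification from domain annotations and G-box motifs.

Septins are P-loop GTPases; their GTPase core carries three diagnostic
sequence motifs ("G boxes"): G1 (the Walker A / P-loop), G3 (the DxxG switch
motif) and G4 (the nucleotide-specificity motif).  A protein is retained as a
septin candidate if it carries a recognized septin domain annotation
(P-Loop_NTPase, CDC3 or CDC_septin), or else at least two of the three G
boxes without a conflicting domain annotation (LysM, DNA_binding).  The
domain route deliberately overrides motif evidence: well-known septins such
as budding-yeast Cdc3 lack recognizable copies of all three boxes.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .errors import InvalidInputError

__all__ = [
    "ProteinRecord",
    "MotifHit",
    "FilterDecision",
    "DEFAULT_GBOX_PATTERNS",
    "SEPTIN_DOMAINS",
    "CONFLICT_DOMAINS",
    "scan_gboxes",
    "classify_candidate",
    "filter_proteome",
    "read_proteome",
    "write_decisions",
    "write_fasta",
]

#: Canonical Ras-superfamily G-box patterns; override per analysis if needed.
DEFAULT_GBOX_PATTERNS: Mapping[str, str] = {
    "G1": r"[AG].{4}GK[ST]",  # Walker A / P-loop
    "G3": r"D.{2}G",          # switch II DxxG
    "G4": r"[NT]K.D",         # nucleotide specificity
}

SEPTIN_DOMAINS = frozenset({"P-Loop_NTPase", "CDC3", "CDC_septin"})
CONFLICT_DOMAINS = frozenset({"LysM", "DNA_binding"})

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")

#: G boxes must appear in genomic order within one GTPase domain; the span
#: from the first to the last retained box is capped (residues).
DEFAULT_MAX_SPAN = 400


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    taxon: str
    sequence: str
    domain_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.sequence:
            raise InvalidInputError(f"protein {self.id!r}: empty sequence")
        if not _AA_RE.match(self.sequence.upper()):
            raise InvalidInputError(
                f"protein {self.id!r}: sequence contains non-amino-acid characters"
            )


@dataclass(frozen=True)
class MotifHit:
    motif_id: str  # G1 | G3 | G4
    start: int     # 1-based
    matched: str


@dataclass(frozen=True)
class FilterDecision:
    id: str
    retained: bool
    reason: str  # domain_pass | gbox_pass | conflict_fail | insufficient_fail


def _all_starts(pattern: str, sequence: str, limit: int = 16) -> list[tuple[int, str]]:
    """0-based starts of (possibly overlapping) matches, leftmost first."""
    out = []
    rx = re.compile(f"(?=({pattern}))")
    for m in rx.finditer(sequence):
        out.append((m.start(), m.group(1)))
        if len(out) >= limit:
            break
    return out


def scan_gboxes(
    sequence: str,
    patterns: Optional[Mapping[str, str]] = None,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[MotifHit]:
    """Scan for G1/G3/G4 boxes, keeping at most one hit per box.

    Among all combinations of candidate matches that respect the genomic
    order G1 < G3 < G4 and lie within ``max_span`` residues of each other,
    the combination with the most boxes is chosen (ties broken by earliest
    start positions).
    """
    if not sequence:
        raise InvalidInputError("empty sequence")
    sequence = sequence.upper()
    patterns = dict(patterns or DEFAULT_GBOX_PATTERNS)
    order = ["G1", "G3", "G4"]
    candidates = {m: _all_starts(patterns[m], sequence) for m in order}

    # Bounded exhaustive search over per-box candidates (or skipping a box):
    # maximize the number of boxes in a consistent ordered chain, breaking
    # ties toward the earliest start positions.
    best_key: Optional[tuple[int, tuple[int, ...]]] = None
    best_choice: tuple[Optional[tuple[int, str]], ...] = (None, None, None)

    def explore(idx: int, choice: list[Optional[tuple[int, str]]]):
        nonlocal best_key, best_choice
        if idx == len(order):
            picked = [c for c in choice if c is not None]
            starts = [c[0] for c in picked]
            if starts and max(starts) - min(starts) > max_span:
                return
            key = (-len(picked), tuple(starts))
            if best_key is None or key < best_key:
                best_key = key
                best_choice = tuple(choice)
            return
        prev = max((c[0] for c in choice if c is not None), default=-1)
        explore(idx + 1, choice + [None])
        for start, matched in candidates[order[idx]]:
            if start > prev:
                explore(idx + 1, choice + [(start, matched)])

    explore(0, [])
    hits = []
    for motif_id, chosen in zip(order, best_choice):
        if chosen is not None:
            start, matched = chosen
            hits.append(MotifHit(motif_id=motif_id, start=start + 1, matched=matched))
    return hits


def classify_candidate(record: ProteinRecord, hits: Sequence[MotifHit]) -> FilterDecision:
    """Apply the retention rule to one protein.

    Domain evidence is checked first and overrides everything; otherwise two
    distinct G boxes suffice unless a conflicting domain is annotated.
    """
    if record.domain_labels & SEPTIN_DOMAINS:
        return FilterDecision(record.id, True, "domain_pass")
    n_boxes = len({h.motif_id for h in hits})
    if n_boxes >= 2:
        if record.domain_labels & CONFLICT_DOMAINS:
            return FilterDecision(record.id, False, "conflict_fail")
        return FilterDecision(record.id, True, "gbox_pass")
    return FilterDecision(record.id, False, "insufficient_fail")


def filter_proteome(
    records: Sequence[ProteinRecord],
    patterns: Optional[Mapping[str, str]] = None,
    max_span: int = DEFAULT_MAX_SPAN,
) -> tuple[list[ProteinRecord], list[FilterDecision]]:
    """Filter a proteome, preserving input order; one decision per input."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInputError(f"duplicate protein ids: {dupes}")
    retained, decisions = [], []
    for record in records:
        decision = classify_candidate(record, scan_gboxes(record.sequence, patterns, max_span))
        decisions.append(decision)
        if decision.retained:
            retained.append(record)
    return retained, decisions


# ---------------------------------------------------------------------------
# I/O

def read_proteome(fasta_path: str, domains_path: str) -> list[ProteinRecord]:
    """Combine a FASTA file and a domain-annotation TSV into ProteinRecords.

    The TSV must have columns protein_id, taxon, domain_labels (comma
    separated, possibly empty); extra columns are ignored.
    """
    meta: dict[str, tuple[str, frozenset[str]]] = {}
    with open(domains_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            labels = frozenset(x for x in row["domain_labels"].split(",") if x)
            meta[row["protein_id"]] = (row["taxon"], labels)
    records = []
    for seq in SeqIO.parse(fasta_path, "fasta"):
        if seq.id not in meta:
            raise InvalidInputError(f"protein {seq.id!r} missing from annotation table")
        taxon, labels = meta[seq.id]
        records.append(ProteinRecord(seq.id, taxon, str(seq.seq), labels))
    return records


def write_decisions(decisions: Iterable[FilterDecision], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "retained", "reason"])
        for d in decisions:
            w.writerow([d.id, int(d.retained), d.reason])


def write_fasta(records: Iterable[ProteinRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")
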