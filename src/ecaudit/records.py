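"""Core record types and record-level transforms.

An EC (Enzyme Commission) class groups enzymes by the reaction they
catalyse, not by sequence.  An annotation audit therefore works on plain
protein records: an accession, the residues, the source superkingdom,
whether the protein has experimental evidence ("characterised"), and its
predicted domain architecture (an ordered list of Pfam-style labels).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

SUPERKINGDOMS = ("Bacteria", "Archaea", "Eukaryota", "Unknown")


@dataclass
class SequenceRecord:
    """One annotated protein sequence.

    Parameters
    ----------
    id:
        Unique accession string (non-empty).
    sequence:
        Amino-acid string; upper-cased on construction.  The 20 standard
        letters plus the ambiguity code ``X`` are expected.
    superkingdom:
        One of ``Bacteria``, ``Archaea``, ``Eukaryota`` or ``Unknown``.
    characterised:
        True when the protein has experimental evidence at protein level
        (SwissProt) or is listed as experimentally tested (BRENDA-style).
    architecture:
        Ordered domain labels along the protein; empty tuple means the
        architecture is unknown.
    """

    id: str
    sequence: str
    superkingdom: str = "Unknown"
    characterised: bool = False
    architecture: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValueError(
                f"record {self.id!r}: superkingdom {self.superkingdom!r} "
                f"not in {SUPERKINGDOMS}"
            )
        self.architecture = tuple(self.architecture)
        if any(not label for label in self.architecture):
            raise ValueError(f"record {self.id!r}: empty domain label")

    def with_architecture(self, architecture: Sequence[str]) -> "SequenceRecord":
        return replace(self, architecture=tuple(architecture))


@dataclass
class AnnotationSnapshot:
    """All records annotated to one EC class in one database version."""

    version_label: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FilterSpec:
    """Length/ambiguity filter applied before any alignment work.

    Defaults follow the audit convention of removing fragments shorter
    than 200 residues, overly long fusions above 580, and sequences
    containing the ambiguity code ``X``.
    """

    min_length: int = 200
    max_length: int = 580
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError(
                f"require 1 <= min_length <= max_length, got "
                f"{self.min_length}..{self.max_length}"
            )


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def deduplicate(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse exact-sequence duplicates, keeping the first-seen record.

    The characterised flag of the retained record is the OR over its
    duplicate group: characterisation is evidence about the sequence,
    not about any single accession carrying it.  Idempotent.
    """
    by_seq: dict[str, SequenceRecord] = {}
    order: list[str] = []
    for rec in records:
        kept = by_seq.get(rec.sequence)
        if kept is None:
            by_seq[rec.sequence] = rec
            order.append(rec.sequence)
        elif rec.characterised and not kept.characterised:
            by_seq[rec.sequence] = replace(kept, characterised=True)
    return [by_seq[s] for s in order]


def filter_sequences(
    records: Sequence[SequenceRecord], spec: FilterSpec = FilterSpec()
) -> tuple[list[SequenceRecord], Counter]:
    """Apply the length/X filter; return kept records and per-reason counts.

    Each removed sequence is counted once under the first matching reason
    in the order ``too_short`` > ``too_long`` > ``ambiguous``, so the
    returned counts plus the kept records partition the input.
    """
    kept: list[SequenceRecord] = []
    removed: Counter = Counter(too_short=0, too_long=0, ambiguous=0)
    for rec in records:
        n = len(rec.sequence)
        if n < spec.min_length:
            removed["too_short"] += 1
        elif n > spec.max_length:
            removed["too_long"] += 1
        elif spec.drop_ambiguous and "X" in rec.sequence:
            removed["ambiguous"] += 1
        else:
            kept.append(rec)
    return kept, removed
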