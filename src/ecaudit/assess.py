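"""Misannotation flags and class-level summaries.

A record annotated to an EC class is suspect when (a) its identity to the
closest characterised class member falls below the twilight-zone
threshold (strictly below 25% by default), (b) its domain architecture
matches no architecture seen among characterised members, or (c) it lacks
conserved catalytic/substrate-binding residues.  The class summary also
produces per-superkingdom identity histograms (bin size 1) and diffs of
annotation snapshots across database versions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .pairwise import (
    AlignParams,
    IdentityResult,
    closest_characterised,
    global_align,
)
from .records import AnnotationSnapshot, SequenceRecord

Architecture = tuple[str, ...]

UNKNOWN_ARCH_LABEL = "unknown"


def architecture_key(architecture: Sequence[str]) -> str:
    """Canonical order-free label for an architecture multiset."""
    if not architecture:
        return UNKNOWN_ARCH_LABEL
    return "+".join(sorted(architecture))


def same_architecture(a: Sequence[str], b: Sequence[str]) -> bool:
    """True iff the domain-label multisets match (order disregarded,
    copy number respected)."""
    return Counter(a) == Counter(b)


def canonical_architectures(
    characterised: Sequence[SequenceRecord],
) -> list[Architecture]:
    """Distinct architecture multisets among characterised records.

    Characterised records with unknown (empty) architectures contribute
    nothing; if none carries an architecture there is no canonical
    reference and the audit cannot score architectures at all.
    """
    seen: dict[tuple[tuple[str, int], ...], Architecture] = {}
    for rec in characterised:
        if not rec.architecture:
            continue
        key = tuple(sorted(Counter(rec.architecture).items()))
        seen.setdefault(key, rec.architecture)
    if not seen:
        raise ValueError("no canonical reference: no characterised record has a known architecture")
    return list(seen.values())


@dataclass(frozen=True)
class ResidueSpec:
    """Conserved active-site residues in an ungapped reference enzyme.

    ``positions`` are 1-based indices into ``reference_id``'s sequence;
    ``expected`` holds the residue letter required at each position.
    """

    reference_id: str
    positions: tuple[int, ...]
    expected: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.expected):
            raise ValueError("positions and expected differ in length")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based")

    def validate_reference(self, reference_sequence: str) -> None:
        for pos, letter in zip(self.positions, self.expected):
            if pos > len(reference_sequence):
                raise ValueError(f"position {pos} beyond reference length")
            if reference_sequence[pos - 1] != letter:
                raise ValueError(
                    f"reference residue at {pos} is "
                    f"{reference_sequence[pos - 1]!r}, spec expects {letter!r}"
                )


def conserved_residues(
    query: SequenceRecord,
    spec: ResidueSpec,
    reference_sequence: str,
    params: AlignParams = AlignParams(),
) -> tuple[dict[int, bool], float]:
    """Check the conserved-residue set in a query via global alignment.

    The query is aligned to the reference; a specified position counts as
    conserved iff the query column aligned to that reference residue holds
    the expected letter.  A reference position that aligns to a gap in the
    query scores not-conserved.  Returns per-position booleans and the
    conserved fraction.
    """
    reference_sequence = reference_sequence.upper()
    spec.validate_reference(reference_sequence)
    ref_aln, query_aln, _ = global_align(reference_sequence, query.sequence, params)
    wanted = dict(zip(spec.positions, spec.expected))
    status: dict[int, bool] = {}
    ref_pos = 0
    for ref_char, q_char in zip(ref_aln, query_aln):
        if ref_char == "-":
            continue
        ref_pos += 1
        if ref_pos in wanted:
            status[ref_pos] = q_char == wanted[ref_pos]
    fraction = sum(status.values()) / len(spec.positions)
    return status, fraction


@dataclass
class MisannotationReport:
    """Per-record flags plus class-level summaries."""

    per_record: dict[str, dict]
    class_summary: dict

    def to_jsonable(self) -> dict:
        return {"per_record": self.per_record, "class_summary": self.class_summary}


def identity_histogram(identities: Sequence[float]) -> list[int]:
    """Counts over bins [0,1), [1,2), ..., [99,100), plus a closed [100]
    bin, so self-matches at exactly 100 stand apart."""
    bins = [0] * 101
    for ident in identities:
        idx = 100 if ident >= 100 else int(ident)
        bins[idx] += 1
    return bins


def classify(
    records: Sequence[SequenceRecord],
    characterised_ids: set[str],
    threshold_pct: float = 25.0,
    residue_spec: Optional[ResidueSpec] = None,
    k: int = 3,
    top_n: int = 1,
    params: AlignParams = AlignParams(),
    include_unknown_in_fraction: bool = False,
) -> MisannotationReport:
    """Flag likely misannotations across an EC class.

    Per record: the maximum identity to the characterised set (NGD
    prefilter + alignment), a strict below-threshold flag, whether the
    architecture matches any canonical (characterised) architecture, and
    optionally the conserved-residue fraction.  Records with unknown
    architectures are scored non-canonical but excluded from the headline
    ``fraction_non_canonical`` denominator unless
    ``include_unknown_in_fraction`` — missing domains in partial genes
    would otherwise inflate the estimate.
    """
    characterised = [r for r in records if r.id in characterised_ids]
    try:
        canon = canonical_architectures(characterised)
    except ValueError:
        canon = []
    reference = None
    if residue_spec is not None:
        matches = [r for r in records if r.id == residue_spec.reference_id]
        if not matches:
            raise ValueError(
                f"residue-spec reference {residue_spec.reference_id!r} "
                f"not among records"
            )
        reference = matches[0]

    per_record: dict[str, dict] = {}
    for rec in records:
        result = closest_characterised(rec, characterised, k=k, top_n=top_n, params=params)
        entry: dict = {
            "max_identity_pct": result.identity_pct,
            "closest_characterised_id": result.subject,
            "below_threshold": result.identity_pct < threshold_pct,
            "architecture_known": bool(rec.architecture),
            "canonical_architecture": bool(rec.architecture)
            and any(same_architecture(rec.architecture, c) for c in canon),
        }
        if residue_spec is not None and reference is not None:
            _, frac = conserved_residues(rec, residue_spec, reference.sequence, params)
            entry["conserved_residue_fraction"] = frac
        else:
            entry["conserved_residue_fraction"] = None
        per_record[rec.id] = entry

    n = len(records)
    n_unknown = sum(1 for e in per_record.values() if not e["architecture_known"])
    arch_denominator = n if include_unknown_in_fraction else n - n_unknown
    n_non_canonical = sum(
        1
        for e in per_record.values()
        if e["architecture_known"] and not e["canonical_architecture"]
    )
    if include_unknown_in_fraction:
        n_non_canonical += n_unknown

    by_kingdom: dict[str, list[float]] = {}
    for rec in records:
        by_kingdom.setdefault(rec.superkingdom, []).append(
            per_record[rec.id]["max_identity_pct"]
        )
    histograms = {sk: identity_histogram(vals) for sk, vals in by_kingdom.items()}

    class_summary = {
        "n": n,
        "n_characterised": len(characterised),
        "n_unknown_architecture": n_unknown,
        "threshold_pct": threshold_pct,
        "fraction_below_threshold": (
            sum(e["below_threshold"] for e in per_record.values()) / n if n else 0.0
        ),
        "fraction_non_canonical": (
            n_non_canonical / arch_denominator if arch_denominator else 0.0
        ),
        "per_superkingdom_histograms": histograms,
    }
    return MisannotationReport(per_record=per_record, class_summary=class_summary)


def architecture_identity_matrix(
    records: Sequence[SequenceRecord],
    groups: Mapping[str, Sequence[str]],
    params: AlignParams = AlignParams(),
) -> dict[tuple[str, str], Optional[float]]:
    """Mean pairwise alignment identity within and between architecture
    groups.

    ``groups`` maps a group label to member accessions.  The (g, g)
    entries are within-group means over all unordered member pairs
    (None for singleton groups); (g, h) entries average all cross pairs.
    """
    by_id = {r.id: r for r in records}
    for label, members in groups.items():
        missing = [m for m in members if m not in by_id]
        if missing:
            raise ValueError(f"group {label!r} references unknown ids {missing}")
    from .pairwise import align_identity

    labels = list(groups)
    out: dict[tuple[str, str], Optional[float]] = {}
    for i, g in enumerate(labels):
        members = list(groups[g])
        pairs = [
            align_identity(by_id[a].sequence, by_id[b].sequence, params)
            for ai, a in enumerate(members)
            for b in members[ai + 1 :]
        ]
        out[(g, g)] = sum(pairs) / len(pairs) if pairs else None
        for h in labels[i + 1 :]:
            cross = [
                align_identity(by_id[a].sequence, by_id[b].sequence, params)
                for a in members
                for b in groups[h]
            ]
            mean = sum(cross) / len(cross) if cross else None
            out[(g, h)] = mean
            out[(h, g)] = mean
    return out


@dataclass
class VersionDiff:
    """Per-architecture record counts in two annotation snapshots."""

    counts: dict[str, tuple[int, int, int]]  # key -> (count_A, count_B, delta)
    totals: tuple[int, int]
    labels: tuple[str, str] = ("A", "B")


def version_diff(
    snapA: AnnotationSnapshot,
    snapB: AnnotationSnapshot,
    domain_table: Optional[Mapping[str, Sequence[str]]] = None,
) -> VersionDiff:
    """Architecture-frequency diff between two (deduplicated) snapshots.

    Architectures come from each record, or from ``domain_table`` when the
    record carries none; records with no architecture anywhere count under
    ``unknown``.  Deltas are count_B - count_A, exposing growth of
    non-canonical families across database versions.
    """

    def arch_counts(snapshot: AnnotationSnapshot) -> Counter:
        counts: Counter = Counter()
        for rec in snapshot.records:
            arch = rec.architecture
            if not arch and domain_table is not None:
                arch = tuple(domain_table.get(rec.id, ()))
            counts[architecture_key(arch)] += 1
        return counts

    a_counts = arch_counts(snapA)
    b_counts = arch_counts(snapB)
    keys = sorted(set(a_counts) | set(b_counts))
    return VersionDiff(
        counts={
            key: (a_counts[key], b_counts[key], b_counts[key] - a_counts[key])
            for key in keys
        },
        totals=(len(snapA.records), len(snapB.records)),
        labels=(snapA.version_label, snapB.version_label),
    )


def write_version_diff_tsv(diff: VersionDiff, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"architecture\tcount_{diff.labels[0]}\tcount_{diff.labels[1]}\tdelta\n")
        for key, (a, b, d) in diff.counts.items():
            fh.write(f"{key}\t{a}\t{b}\t{d:+d}\n")


def write_report_tsv(report: MisannotationReport, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "id\tmax_identity_pct\tclosest_characterised_id\tbelow_threshold\t"
            "canonical_architecture\tarchitecture_known\tconserved_residue_fraction\n"
        )
        for acc, e in report.per_record.items():
            frac = e["conserved_residue_fraction"]
            fh.write(
                f"{acc}\t{e['max_identity_pct']:.4f}\t"
                f"{e['closest_characterised_id'] or ''}\t"
                f"{int(e['below_threshold'])}\t{int(e['canonical_architecture'])}\t"
                f"{int(e['architecture_known'])}\t"
                f"{'' if frac is None else f'{frac:.4f}'}\n"
            )
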