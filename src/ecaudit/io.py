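"""Readers and writers for the pipeline's plain-text interfaces.

Formats: FASTA (sequences), a TSV domain table (``id<TAB>domain<TAB>start``,
1-based inclusive start coordinates), BLAST tabular ``-outfmt 6``, and a
characterised-id list with one accession per line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import SequenceRecord, check_unique_ids

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into SequenceRecords.

    The header token before the first whitespace becomes the record id;
    sequences are upper-cased.  A file whose first non-blank line does not
    start with ``>`` is rejected with the offending line number.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA, line {lineno} does not "
                        f"start with '>'"
                    )
                break
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column line wrapping."""
    bio = [
        BioSeqRecord(Seq(rec.sequence), id=rec.id, description="")
        for rec in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_id_list(path: str | Path) -> set[str]:
    """One accession per line; blank lines and ``#`` comments ignored."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            ids.add(token)
    return ids


def read_domain_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Parse the per-sequence domain table into id -> ordered labels.

    Rows carry one domain hit each (columns ``id``, ``domain``, ``start``);
    per id, domains are ordered by ascending 1-based start coordinate.
    A non-integer start or a duplicate (id, start) pair is an error.  Ids
    absent from the table simply have no entry; callers treat a missing id
    as an unknown (empty) architecture.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "domain", "start"],
                     dtype=str, comment="#", skip_blank_lines=True)
    if df["id"].astype(str).iloc[0:1].tolist() == ["id"]:  # optional header row
        df = df.iloc[1:]
    try:
        starts = df["start"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-integer start coordinate ({exc})") from None
    df = df.assign(start=starts)
    dup = df.duplicated(subset=["id", "start"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (id, start) pair ({row['id']}, {row['start']})"
        )
    table: dict[str, tuple[str, ...]] = {}
    for acc, group in df.groupby("id", sort=False):
        table[str(acc)] = tuple(group.sort_values("start")["domain"].astype(str))
    return table


def write_domain_table(
    architectures: Mapping[str, Sequence[str]], path: str | Path
) -> None:
    """Inverse of :func:`read_domain_table` with synthetic 1,101,201... starts."""
    with Path(path).open("w") as fh:
        for acc, labels in architectures.items():
            for i, label in enumerate(labels):
                fh.write(f"{acc}\t{label}\t{1 + 100 * i}\n")


def read_blast_tab(path: str | Path) -> list[tuple[str, str, float, float]]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``).

    Returns (query, subject, bitscore, evalue) tuples.  Self-hits are
    retained (downstream graph construction ignores them); duplicate
    (query, subject) pairs keep the best bitscore.
    """
    path = Path(path)
    best: dict[tuple[str, str], tuple[str, str, float, float]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} columns, "
                    f"expected 12 (outfmt 6)"
                )
            q, s = fields[0], fields[1]
            evalue, bitscore = float(fields[10]), float(fields[11])
            key = (q, s)
            if key not in best or bitscore > best[key][2]:
                best[key] = (q, s, bitscore, evalue)
    return list(best.values())


def write_identity_tsv(results: Iterable, path: str | Path) -> None:
    """Write IdentityResults as TSV (see :mod:`ecaudit.pairwise`)."""
    with Path(path).open("w") as fh:
        fh.write("query\tsubject\tidentity_pct\tmatches\taligned_columns\t"
                 "prefilter_distance\n")
        for r in results:
            subj = r.subject if r.subject is not None else ""
            dist = "" if r.prefilter_distance is None else f"{r.prefilter_distance:.6f}"
            fh.write(f"{r.query}\t{subj}\t{r.identity_pct:.4f}\t{r.matches}\t"
                     f"{r.aligned_columns}\t{dist}\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
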