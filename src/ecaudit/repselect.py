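"""Entropy-guided selection of representative sequences from a cluster MSA.

Each column of a multiple sequence alignment carries Shannon entropy
H_j = -sum_a p_ja log2 p_ja over the 20 amino acids plus the gap symbol.
A subset S of rows "explains" at column j the probability mass of the
symbols it exhibits there; the alignment-wide explained information is the
entropy-weighted mean of that coverage:

    explained(S) = sum_j H_j * c_j(S) / sum_j H_j,
    c_j(S) = sum over symbols shown by S at column j of p_ja.

This objective is monotone and submodular, so greedy selection — add the
row with the largest marginal gain until the target fraction (default
0.85) is explained — is the principled strategy.  An alignment with no
variable columns carries no information; a single sequence then explains
everything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pairwise import AlignParams, global_align
from .records import SequenceRecord

GAP = "-"


@dataclass
class MSAView:
    """A rectangular multiple sequence alignment."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows:
            raise ValueError("empty MSA")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("MSA rows differ in length")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def column_frequencies(self, j: int) -> dict[str, float]:
        col = self.column(j)
        return {sym: col.count(sym) / len(col) for sym in set(col)}


@dataclass
class SelectionResult:
    """Greedily selected representatives with per-step explained fractions."""

    selected: list[str]
    explained_after_step: list[float]
    target: float
    total_information: float  # bits, summed over columns

    def __post_init__(self) -> None:
        steps = self.explained_after_step
        if any(b < a - 1e-12 for a, b in zip(steps, steps[1:])):
            raise ValueError("explained_after_step must be non-decreasing")


def column_entropy(msa: MSAView) -> np.ndarray:
    """Per-column Shannon entropy in bits; the gap counts as a symbol."""
    out = np.zeros(msa.length)
    for j in range(msa.length):
        freqs = np.array(list(msa.column_frequencies(j).values()))
        out[j] = float(-(freqs * np.log2(freqs)).sum())
    return out


def information_explained(msa: MSAView, subset: Sequence[str]) -> float:
    """Entropy-weighted symbol-mass coverage of a row subset (see module
    docstring).  Empty subset -> 0; full set -> 1; an all-invariant MSA is
    fully explained by any non-empty subset."""
    subset_set = set(subset)
    unknown = subset_set - set(msa.ids)
    if unknown:
        raise ValueError(f"subset ids not in MSA: {sorted(unknown)}")
    if not subset_set:
        return 0.0
    H = column_entropy(msa)
    total = H.sum()
    if total == 0:
        return 1.0
    row_idx = [i for i, acc in enumerate(msa.ids) if acc in subset_set]
    covered = 0.0
    for j in np.nonzero(H)[0]:
        freqs = msa.column_frequencies(j)
        shown = {msa.rows[i][j] for i in row_idx}
        covered += H[j] * sum(freqs[s] for s in shown)
    return covered / total


def select_representatives(
    msa: MSAView, target: float = 0.85
) -> SelectionResult:
    """Greedy selection until ``target`` of the MSA's information is
    explained.

    At each step the row with the largest marginal increase in explained
    information joins the selection (ties resolved to the lowest row
    index), stopping once the target is reached or every row is selected.
    """
    if not (0 < target <= 1):
        raise ValueError("target must be in (0, 1]")
    H = column_entropy(msa)
    total = float(H.sum())
    variable = np.nonzero(H)[0]
    freqs = {j: msa.column_frequencies(j) for j in variable}

    selected_idx: list[int] = []
    shown: dict[int, set[str]] = {j: set() for j in variable}
    explained_steps: list[float] = []
    explained = 0.0

    def gain(i: int) -> float:
        g = 0.0
        for j in variable:
            sym = msa.rows[i][j]
            if sym not in shown[j]:
                g += H[j] * freqs[j][sym]
        return g

    while len(selected_idx) < msa.n:
        if total == 0:
            best_i = 0 if not selected_idx else None
            if best_i is None:
                break
            selected_idx.append(best_i)
            explained_steps.append(1.0)
            explained = 1.0
        else:
            remaining = [i for i in range(msa.n) if i not in selected_idx]
            gains = [gain(i) for i in remaining]
            best_pos = int(np.argmax(gains))  # argmax keeps lowest index on ties
            best_i = remaining[best_pos]
            selected_idx.append(best_i)
            for j in variable:
                shown[j].add(msa.rows[best_i][j])
            explained = sum(
                H[j] * sum(freqs[j][s] for s in shown[j]) for j in variable
            ) / total
            explained_steps.append(float(explained))
        if explained >= target:
            break
    return SelectionResult(
        selected=[msa.ids[i] for i in selected_idx],
        explained_after_step=explained_steps,
        target=target,
        total_information=total,
    )


def read_aligned_fasta(path: str | Path) -> MSAView:
    """Read an externally produced alignment (gapped FASTA) as-is."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MSAView(ids=ids, rows=rows)


def center_star_msa(
    records: Sequence[SequenceRecord], params: AlignParams = AlignParams()
) -> MSAView:
    """Multiple alignment by the center-star heuristic.

    The longest sequence (ties by id) is the center; every other sequence
    is globally aligned to it and the pairwise alignments are merged with
    the once-a-gap-always-a-gap rule.  Adequate for entropy bookkeeping on
    within-cluster alignments; not a substitute for a progressive aligner
    on deeply divergent sets.
    """
    if not records:
        raise ValueError("no records")
    if len(records) == 1:
        return MSAView(ids=[records[0].id], rows=[records[0].sequence])
    center = min(records, key=lambda r: (-len(r.sequence), r.id))
    others = [r for r in records if r.id != center.id]

    master = center.sequence  # center row, gaps accumulate
    rows: list[str] = []  # non-center rows aligned to master
    ids: list[str] = []
    for rec in others:
        c_aln, s_aln, _ = global_align(center.sequence, rec.sequence, params)
        master, rows, s_merged = _merge(master, rows, c_aln, s_aln)
        rows.append(s_merged)
        ids.append(rec.id)
    return MSAView(ids=[center.id, *ids], rows=[master, *rows])


def _merge(
    master: str, rows: list[str], c_aln: str, s_aln: str
) -> tuple[str, list[str], str]:
    """Merge a new (center, seq) pairwise alignment into the running MSA.

    ``master`` and ``c_aln`` are the same center sequence under different
    gap placements; walk both, inserting gaps so every existing row and
    the new row agree on one master coordinate system.
    """
    new_master: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_s: list[str] = []
    i = j = 0
    while i < len(master) or j < len(c_aln):
        a = master[i] if i < len(master) else None
        b = c_aln[j] if j < len(c_aln) else None
        if a is not None and b is not None and (a == b != GAP or (a == GAP and b == GAP)):
            new_master.append(a)
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_s.append(s_aln[j])
            i += 1
            j += 1
        elif a == GAP and (b != GAP or b is None):
            new_master.append(GAP)
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_s.append(GAP)
            i += 1
        elif b == GAP and (a != GAP or a is None):
            new_master.append(GAP)
            for r in new_rows:
                r.append(GAP)
            new_s.append(s_aln[j])
            j += 1
        else:  # residues disagree: impossible for the same center sequence
            raise AssertionError("center sequences diverged during merge")
    return (
        "".join(new_master),
        ["".join(r) for r in new_rows],
        "".join(new_s),
    )


def write_selection_tsv(result: SelectionResult, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("step\tid\texplained_after_step\n")
        for step, (acc, expl) in enumerate(
            zip(result.selected, result.explained_after_step), start=1
        ):
            fh.write(f"{step}\t{acc}\t{expl:.6f}\n")


def write_selection_json(result: SelectionResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "selected": result.selected,
                "explained_after_step": result.explained_after_step,
                "target": result.target,
                "total_information_bits": result.total_information,
            },
            indent=2,
        )
        + "\n"
    )
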