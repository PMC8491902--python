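"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ecaudit.records import SequenceRecord
from ecaudit.simulate import ClassConfig, generate_ec_class, random_sequence, mutate_to_identity

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_align_score(
    a: str, b: str, gap_open: float = -10.0, gap_extend: float = -0.5
) -> float:
    """Optimal global-alignment score by exhaustive enumeration.

    Walks every monotone alignment path, scoring matches with BLOSUM62
    and gaps with the affine convention (a run of length L costs
    open + (L-1)*extend, terminal runs included).  Only feasible for very
    short sequences; serves as the independent optimum oracle.
    """
    best = -math.inf

    def rec(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + BLOSUM62[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "D", score + (gap_extend if prev == "D" else gap_open))
        if j < len(b):
            rec(i, j + 1, "I", score + (gap_extend if prev == "I" else gap_open))

    rec(0, 0, "", 0.0)
    return best


def make_identity_ladder(seed: int, n: int, length: int = 350,
                         lowest: float = 0.10) -> list[SequenceRecord]:
    """A family 'ladder': one root plus mutants at identities stepping
    down from 0.95 to ``lowest`` — a graded test bed for prefilter vs
    alignment rank agreement."""
    rng = np.random.default_rng(seed)
    root = random_sequence(length, rng)
    records = [SequenceRecord(id="L000", sequence=root)]
    targets = np.linspace(0.95, lowest, n - 1)
    for i, t in enumerate(targets, start=1):
        records.append(
            SequenceRecord(
                id=f"L{i:03d}",
                sequence=mutate_to_identity(root, float(t), 0.0, rng),
            )
        )
    return records


@pytest.fixture(scope="session")
def ec_class_42():
    """The reference synthetic class: 60 canonical members (5
    characterised, shared architecture) + 40 outliers in two divergent
    families with distinct architectures."""
    return generate_ec_class(ClassConfig(seed=42))


@pytest.fixture(scope="session")
def small_class():
    """A small three-family class for clustering tests (within-family
    identity >= 70%, between-family roots < 25%)."""
    config = ClassConfig(
        seed=7,
        family_sizes=(8, 8, 8),
        root_length=250,
        within_identity=(0.75, 0.95),
        characterised_per_family=(2, 0, 0),
        architectures=(("FMN_dh",), ("DAO",), ("CCG",)),
        indel_rate=0.0,
        max_root_identity=25.0,
    )
    return generate_ec_class(config)
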