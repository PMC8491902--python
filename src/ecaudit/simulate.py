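"""Synthetic EC-class generator with ground truth.

Real audit inputs come from enzyme databases; tests and examples instead
use simulated classes that reproduce the structure the analysis assumes:
one canonical family (sharing a canonical architecture and containing the
characterised members) plus several unrelated families with distinct
architectures and sub-30% identity roots — the planted "misannotated"
records.  Taxonomy labels, kinetics tables and screening plates are
generated the same way, all deterministically from one seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import write_domain_table, write_fasta
from .kinetics import PlateMeasurement, detection_limit
from .pairwise import AlignParams, align_identity
from .records import AnnotationSnapshot, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Background residue frequencies underlying the BLOSUM62 matrix (Robinson &
# Robinson counts, normalised); used for the more realistic root model whose
# unrelated-pair identities land in the observed ~15-20% twilight zone.
BLOSUM_BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}


@dataclass
class ClassConfig:
    """Shape of one synthetic EC class.

    Defaults produce the audit's reference scenario: a canonical family
    with five characterised members plus divergent outlier families, all
    sequences inside the 200-580 length filter.
    """

    seed: int = 0
    family_sizes: tuple[int, ...] = (60, 20, 20)
    root_length: int = 350
    within_identity: tuple[float, float] = (0.70, 0.95)
    canonical_family_index: int = 0
    characterised_per_family: tuple[int, ...] = (5, 0, 0)
    architectures: tuple[tuple[str, ...], ...] = (
        ("FMN_dh",),
        ("DAO",),
        ("FAD_binding_4", "FAD_oxidase_C"),
    )
    superkingdom_weights: dict = field(
        default_factory=lambda: {"Bacteria": 0.9, "Eukaryota": 0.07, "Archaea": 0.03}
    )
    indel_rate: float = 0.01
    background: str = "uniform"  # uniform | blosum
    max_root_identity: float = 30.0

    def __post_init__(self) -> None:
        if len(self.family_sizes) < 1:
            raise ValueError("need at least one family")
        if not (0 <= self.canonical_family_index < len(self.family_sizes)):
            raise ValueError("canonical_family_index out of range")
        if len(self.characterised_per_family) != len(self.family_sizes):
            raise ValueError("characterised_per_family length mismatch")
        if len(self.architectures) != len(self.family_sizes):
            raise ValueError("architectures length mismatch")
        if len({tuple(sorted(a)) for a in self.architectures}) != len(
            self.architectures
        ):
            raise ValueError("family architectures must be pairwise distinct")
        lo, hi = self.within_identity
        if not (0 < lo <= hi <= 1):
            raise ValueError("within_identity must satisfy 0 < lo <= hi <= 1")


def random_sequence(length: int, rng: np.random.Generator,
                    background: str = "uniform") -> str:
    if background == "uniform":
        return "".join(rng.choice(list(AMINO_ACIDS), size=length))
    if background == "blosum":
        letters = list(BLOSUM_BACKGROUND)
        probs = np.array(list(BLOSUM_BACKGROUND.values()))
        probs = probs / probs.sum()
        return "".join(rng.choice(letters, size=length, p=probs))
    raise ValueError(f"unknown background {background!r}")


def mutate_to_identity(
    sequence: str,
    target_identity: float,
    indel_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Mutate a sequence to an exact substitution identity, then indels.

    Exactly ceil((1 - target) * L) positions, chosen without replacement,
    are substituted to a different residue (uniform over the other 19), so
    the ungapped identity before indels is 1 - substituted/L exactly.
    Single-residue insertions/deletions then fire per site at
    ``indel_rate``.  Targets below 0.05 are refused — they fall under the
    random-identity floor of unrelated proteins.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity < 0.05:
        raise ValueError("target identity below random-identity floor")
    L = len(sequence)
    n_sub = math.ceil((1 - target_identity) * L)
    out = list(sequence)
    for pos in rng.choice(L, size=n_sub, replace=False):
        current = out[pos]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    if indel_rate > 0:
        result: list[str] = []
        for ch in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            if r < indel_rate:
                result.append("".join(rng.choice(list(AMINO_ACIDS), size=1)))
            result.append(ch)
        out = result if result else out
    return "".join(out)


def generate_family(
    root: str,
    n: int,
    within_identity: tuple[float, float],
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> list[str]:
    """Root plus n-1 mutants at identities drawn from the given interval."""
    if n < 1:
        raise ValueError("family size must be >= 1")
    members = [root]
    lo, hi = within_identity
    for _ in range(n - 1):
        target = float(rng.uniform(lo, hi))
        members.append(mutate_to_identity(root, target, indel_rate, rng))
    return members


def generate_ec_class(
    config: ClassConfig,
) -> tuple[AnnotationSnapshot, dict[str, dict]]:
    """Generate one synthetic class and its ground truth.

    Family roots are drawn independently and re-drawn (up to 100 times)
    until every root pair aligns below ``max_root_identity`` percent, so
    outlier families genuinely sit outside the twilight zone of the
    canonical one.  Ground truth maps each accession to its family index,
    misannotation status (family != canonical), superkingdom and
    architecture.
    """
    rng = np.random.default_rng(config.seed)
    params = AlignParams()
    roots: list[str] = []
    for fam in range(len(config.family_sizes)):
        for attempt in range(100):
            candidate = random_sequence(config.root_length, rng, config.background)
            if all(
                align_identity(candidate, r, params) < config.max_root_identity
                for r in roots
            ):
                roots.append(candidate)
                break
        else:
            raise RuntimeError(
                "root rejection sampling failed 100 times; roots too "
                "similar — increase root_length"
            )

    kingdoms = list(config.superkingdom_weights)
    kweights = np.array(list(config.superkingdom_weights.values()), dtype=float)
    kweights = kweights / kweights.sum()

    records: list[SequenceRecord] = []
    truth: dict[str, dict] = {}
    for fam, (size, root) in enumerate(zip(config.family_sizes, roots)):
        seqs = generate_family(
            root, size, config.within_identity, rng, config.indel_rate
        )
        arch = config.architectures[fam]
        n_char = config.characterised_per_family[fam]
        for i, seq in enumerate(seqs):
            acc = f"SYN{fam}_{i:03d}"
            kingdom = kingdoms[rng.choice(len(kingdoms), p=kweights)]
            rec = SequenceRecord(
                id=acc,
                sequence=seq,
                superkingdom=kingdom,
                characterised=i < n_char,
                architecture=arch,
            )
            records.append(rec)
            truth[acc] = {
                "family_index": fam,
                "is_misannotated": fam != config.canonical_family_index,
                "superkingdom": kingdom,
                "architecture": list(arch),
            }
    snapshot = AnnotationSnapshot(
        version_label=f"synthetic-seed{config.seed}", records=records
    )
    return snapshot, truth


def write_class_files(
    snapshot: AnnotationSnapshot,
    truth: dict[str, dict],
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit FASTA + domain TSV + characterised-id list + truth JSON —
    exactly the file contract the audit pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "class.fasta",
        "domains": outdir / "domains.tsv",
        "characterised": outdir / "characterised.txt",
        "truth": outdir / "truth.json",
    }
    write_fasta(snapshot.records, paths["fasta"])
    write_domain_table(
        {r.id: r.architecture for r in snapshot.records if r.architecture},
        paths["domains"],
    )
    paths["characterised"].write_text(
        "".join(f"{r.id}\n" for r in snapshot.records if r.characterised)
    )
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths


def generate_kinetic_data(
    K_M: float,
    V_max: float,
    concentrations: Sequence[float],
    noise_cv: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Michaelis-Menten velocities with multiplicative Gaussian noise."""
    if K_M <= 0 or V_max <= 0:
        raise ValueError("K_M and V_max must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    S = np.asarray(concentrations, dtype=float)
    v = V_max * S / (K_M + S)
    if noise_cv > 0:
        v = v * (1 + rng.normal(0, noise_cv, size=S.shape))
    return S, v


def generate_plate(
    n_hits: int,
    n_nonhits: int,
    lod_margin: float = 50.0,
    rng: Optional[np.random.Generator] = None,
    n_replicates: int = 3,
    blank_mean: float = 100.0,
    blank_sd: float = 5.0,
) -> tuple[list[PlateMeasurement], list[float], dict[str, bool]]:
    """Synthetic endpoint plate with known hit labels.

    Blank replicates define the LOD; true hits get all replicates above
    LOD + margin and all-soluble calls, non-hits stay a margin below LOD
    with one soluble call only.  Returns (measurements, blanks, truth).
    """
    if rng is None:
        rng = np.random.default_rng()
    blanks = list(rng.normal(blank_mean, blank_sd, size=6))
    lod = detection_limit(blanks, 4.0)
    measurements: list[PlateMeasurement] = []
    truth: dict[str, bool] = {}
    for i in range(n_hits):
        acc = f"HIT{i:03d}"
        signals = list(lod + lod_margin + rng.normal(0, blank_sd, n_replicates))
        measurements.append(
            PlateMeasurement(
                protein_id=acc,
                substrate="substrate",
                signals=signals,
                controls=[0.0] * n_replicates,
                soluble_calls=[True] * n_replicates,
            )
        )
        truth[acc] = True
    for i in range(n_nonhits):
        acc = f"NEG{i:03d}"
        signals = list(
            np.clip(lod - lod_margin + rng.normal(0, blank_sd, n_replicates), 0, None)
        )
        measurements.append(
            PlateMeasurement(
                protein_id=acc,
                substrate="substrate",
                signals=signals,
                controls=[0.0] * n_replicates,
                soluble_calls=[True, False, False],
            )
        )
        truth[acc] = False
    return measurements, blanks, truth
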