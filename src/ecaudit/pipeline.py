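"""End-to-end audit orchestration.

``run_audit`` wires the stages together: read inputs -> length/X filter ->
deduplicate -> (optional greedy 90% clustering with characterised members
restored) -> MCL clustering of the class -> per-cluster MSA + entropy
selection -> misannotation classification -> artifacts on disk
(report.json, per_record.tsv, clusters.tsv, selection.tsv,
histograms.tsv).  ``run_versions`` diffs two annotation snapshots.
Everything is deterministic given the config.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import assess, clustering, io, repselect
from .pairwise import AlignParams
from .records import (
    AnnotationSnapshot,
    FilterSpec,
    SequenceRecord,
    deduplicate,
    filter_sequences,
)

log = logging.getLogger("ecaudit")


@dataclass
class PipelineConfig:
    """Inputs, constants and output location for one audit run.

    The defaults are the audit's standard constants: k-tuple word size 3
    for the prefilter, word size 5 for the greedy prescreen, MCL inflation
    1.4, 90% greedy clustering threshold, 85% selection target, and the
    25% twilight-zone identity threshold.
    """

    fasta: Path
    domain_table: Optional[Path] = None
    characterised_list: Optional[Path] = None
    blast_tab: Optional[Path] = None
    residue_spec: Optional[Path] = None
    outdir: Path = Path("ecaudit_out")
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    align_params: AlignParams = field(default_factory=AlignParams)
    k: int = 3
    top_n: int = 1
    cluster_method: str = "mcl"  # mcl | greedy
    inflation: float = 1.4
    greedy_threshold_pct: float = 90.0
    greedy_prefilter_k: int = 5
    min_edge_identity: float = 30.0
    selection_target: float = 0.85
    identity_threshold_pct: float = 25.0
    seed: int = 0


@dataclass
class AuditResult:
    report: assess.MisannotationReport
    clusters: clustering.ClusterSet
    selections: dict[int, repselect.SelectionResult]
    records: list[SequenceRecord]
    artifacts: dict[str, Path]


def load_records(config: PipelineConfig) -> list[SequenceRecord]:
    records = io.read_fasta(config.fasta)
    if config.domain_table is not None:
        table = io.read_domain_table(config.domain_table)
        records = [r.with_architecture(table.get(r.id, ())) for r in records]
    if config.characterised_list is not None:
        char_ids = io.read_id_list(config.characterised_list)
        records = [
            SequenceRecord(
                id=r.id,
                sequence=r.sequence,
                superkingdom=r.superkingdom,
                characterised=r.id in char_ids,
                architecture=r.architecture,
            )
            for r in records
        ]
    return records


def run_audit(config: PipelineConfig) -> AuditResult:
    """Execute the full audit and write artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = load_records(config)
    log.info("loaded %d records from %s", len(records), config.fasta)

    kept, removed = filter_sequences(records, config.filter_spec)
    log.info(
        "filter: kept %d, removed %s", len(kept), dict(removed)
    )
    records = deduplicate(kept)
    log.info("deduplicate: %d unique sequences", len(records))

    characterised_ids = {r.id for r in records if r.characterised}
    if not characterised_ids:
        warnings.warn(
            "no characterised sequences: all identities will be 0 and no "
            "canonical architecture exists"
        )

    by_id = {r.id: r for r in records}

    # analysis set: optionally collapse redundancy at 90% identity first
    if config.cluster_method == "greedy":
        greedy = clustering.greedy_identity_cluster(
            records,
            threshold_pct=config.greedy_threshold_pct,
            prefilter_k=config.greedy_prefilter_k,
            params=config.align_params,
        )
        analysis_ids = clustering.restore_characterised(greedy, characterised_ids)
        analysis_records = [by_id[a] for a in analysis_ids]
        log.info(
            "greedy clustering: %d clusters, analysis set %d",
            len(greedy.clusters),
            len(analysis_records),
        )
    else:
        analysis_records = records

    # family structure of the analysis set via MCL
    if config.blast_tab is not None:
        graph = clustering.graph_from_blast(io.read_blast_tab(config.blast_tab))
    else:
        graph = clustering.build_similarity_graph(
            analysis_records,
            params=config.align_params,
            min_identity=config.min_edge_identity,
        )
    clusters = clustering.mcl(graph, inflation=config.inflation)
    log.info("MCL: %d clusters at inflation %.2f", len(clusters.clusters), config.inflation)

    # per-cluster MSA + representative selection
    selections: dict[int, repselect.SelectionResult] = {}
    for ci, members in enumerate(clusters.clusters):
        cluster_records = [by_id[m] for m in members if m in by_id]
        if not cluster_records:
            continue
        msa = repselect.center_star_msa(cluster_records, config.align_params)
        selections[ci] = repselect.select_representatives(
            msa, target=config.selection_target
        )
    log.info("selection: %d clusters processed", len(selections))

    residue_spec = None
    if config.residue_spec is not None:
        import json

        raw = json.loads(Path(config.residue_spec).read_text())
        residue_spec = assess.ResidueSpec(
            reference_id=raw["reference_id"],
            positions=tuple(raw["positions"]),
            expected=tuple(raw["expected"]),
        )

    report = assess.classify(
        records,
        characterised_ids,
        threshold_pct=config.identity_threshold_pct,
        residue_spec=residue_spec,
        k=config.k,
        top_n=config.top_n,
        params=config.align_params,
    )
    log.info(
        "classify: fraction_non_canonical=%.3f fraction_below_threshold=%.3f",
        report.class_summary["fraction_non_canonical"],
        report.class_summary["fraction_below_threshold"],
    )

    artifacts = {
        "report": outdir / "report.json",
        "per_record": outdir / "per_record.tsv",
        "clusters": outdir / "clusters.tsv",
        "selection": outdir / "selection.tsv",
        "histograms": outdir / "histograms.tsv",
    }
    io.write_json(report.to_jsonable(), artifacts["report"])
    assess.write_report_tsv(report, artifacts["per_record"])
    clustering.write_clusters_tsv(clusters, artifacts["clusters"])
    with artifacts["selection"].open("w") as fh:
        fh.write("cluster_index\tstep\tid\texplained_after_step\n")
        for ci, sel in selections.items():
            for step, (acc, expl) in enumerate(
                zip(sel.selected, sel.explained_after_step), start=1
            ):
                fh.write(f"{ci}\t{step}\t{acc}\t{expl:.6f}\n")
    with artifacts["histograms"].open("w") as fh:
        fh.write("superkingdom\tbin_low\tcount\n")
        for sk, bins in report.class_summary["per_superkingdom_histograms"].items():
            for low, count in enumerate(bins):
                fh.write(f"{sk}\t{low}\t{count}\n")

    return AuditResult(
        report=report,
        clusters=clusters,
        selections=selections,
        records=records,
        artifacts=artifacts,
    )


def run_versions(
    fasta_a: Path,
    fasta_b: Path,
    label_a: str,
    label_b: str,
    domain_table: Optional[Path] = None,
    outdir: Path = Path("ecaudit_out"),
) -> assess.VersionDiff:
    """Deduplicate two snapshots and write their architecture diff."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = io.read_domain_table(domain_table) if domain_table else None

    def snapshot(path: Path, label: str) -> AnnotationSnapshot:
        records = deduplicate(io.read_fasta(path))
        log.info("%s: %d unique records", label, len(records))
        return AnnotationSnapshot(version_label=label, records=records)

    diff = assess.version_diff(snapshot(fasta_a, label_a), snapshot(fasta_b, label_b), table)
    assess.write_version_diff_tsv(diff, outdir / "version_diff.tsv")
    return diff
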