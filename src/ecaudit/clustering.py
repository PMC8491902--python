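"""Two clustering routes over an EC class.

For sequence selection the class is clustered with the Markov Cluster
algorithm (MCL) on an all-vs-all similarity graph (inflation 1.4).  For
database-wide audits a greedy incremental clustering at 90% identity with
a word-size-5 shared-k-mer prescreen collapses redundant sequencing of the
same organism, after which characterised members that were absorbed into
clusters are restored to the analysis set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .pairwise import AlignParams, align_identity
from .records import SequenceRecord


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over accessions (no self-loops stored)."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    weight_kind: str = "identity"  # bitscore | neg_log_evalue | identity

    def __post_init__(self) -> None:
        index = {n: i for i, n in enumerate(self.nodes)}
        if len(index) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in index or b not in index:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"edge ({a}, {b}) has invalid weight {w}")

    def adjacency(self) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.nodes)}
        mat = np.zeros((len(self.nodes), len(self.nodes)))
        for a, b, w in self.edges:
            i, j = index[a], index[b]
            mat[i, j] = max(mat[i, j], w)
            mat[j, i] = mat[i, j]
        return mat

    def degree(self, node: str) -> int:
        return sum(1 for a, b, _ in self.edges if node in (a, b))


@dataclass
class ClusterSet:
    """A partition of accessions with one representative per cluster."""

    clusters: list[list[str]]
    representatives: list[str]
    method: str
    params_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = [m for c in self.clusters for m in c]
        if len(members) != len(set(members)):
            raise ValueError("clusters do not partition the node set")
        for rep, cluster in zip(self.representatives, self.clusters):
            if rep not in cluster:
                raise ValueError(f"representative {rep!r} not in its cluster")

    def labels(self) -> dict[str, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c}


def build_similarity_graph(
    records: Sequence[SequenceRecord],
    params: AlignParams = AlignParams(),
    min_identity: float = 30.0,
) -> SimilarityGraph:
    """All-vs-all alignment-identity graph.

    Pairs below ``min_identity`` percent get no edge, mirroring an
    all-vs-all BLAST where unrelated pairs simply produce no significant
    hit; the resulting sparsity is what lets MCL resolve families.
    """
    nodes = [r.id for r in records]
    edges: list[tuple[str, str, float]] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            ident = align_identity(records[i].sequence, records[j].sequence, params)
            if ident >= min_identity:
                edges.append((records[i].id, records[j].id, ident))
    return SimilarityGraph(nodes=nodes, edges=edges, weight_kind="identity")


def graph_from_blast(
    hits: Iterable[tuple[str, str, float, float]],
    weight_kind: str = "bitscore",
) -> SimilarityGraph:
    """Build a graph from parsed BLAST tabular hits (self-hits ignored)."""
    nodes: list[str] = []
    seen: set[str] = set()
    best: dict[tuple[str, str], float] = {}
    for q, s, bitscore, evalue in hits:
        for n in (q, s):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
        if q == s:
            continue
        if weight_kind == "bitscore":
            w = bitscore
        elif weight_kind == "neg_log_evalue":
            w = -np.log10(evalue) if evalue > 0 else 400.0
        else:
            raise ValueError(f"unknown weight_kind {weight_kind!r}")
        key = (min(q, s), max(q, s))
        best[key] = max(best.get(key, 0.0), w)
    edges = [(a, b, w) for (a, b), w in best.items()]
    return SimilarityGraph(nodes=nodes, edges=edges, weight_kind=weight_kind)


class MCLConvergenceWarning(UserWarning):
    pass


def mcl(
    graph: SimilarityGraph,
    inflation: float = 1.4,
    max_iter: int = 100,
    prune_below: float = 1e-5,
) -> ClusterSet:
    """Markov clustering of a similarity graph.

    The adjacency matrix gains self-loops weighted by each node's maximum
    incident edge weight (weight 1 for isolated nodes), is column
    normalised, then iterated with expansion (matrix square) and inflation
    (elementwise power ``inflation`` + renormalisation), pruning entries
    below ``prune_below``, until the matrix changes by less than 1e-8.
    Clusters are read from attractor rows (positive diagonal); overlapping
    attractor rows are merged.  The representative of each cluster is its
    highest-degree member, ties broken by lexicographic id.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if not graph.nodes:
        raise ValueError("empty graph")
    n = len(graph.nodes)
    mat = graph.adjacency()
    loops = mat.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(mat, loops)
    mat = mat / mat.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        new = mat @ mat
        new = np.power(new, inflation)
        new[new < prune_below] = 0.0
        colsums = new.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        new = new / colsums
        if np.abs(new - mat).max() < 1e-8:
            mat = new
            converged = True
            break
        mat = new
    if not converged:
        warnings.warn(
            f"MCL did not converge in {max_iter} iterations; reading "
            f"clusters from the current matrix",
            MCLConvergenceWarning,
        )

    # attractor rows -> clusters; union overlapping attractor supports
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    attractors = [i for i in range(n) if mat[i, i] > 1e-6]
    membership = [-1] * n
    for i in attractors:
        support = np.nonzero(mat[i] > 0)[0]
        for j in support:
            if membership[j] == -1:
                membership[j] = i
            else:
                union(membership[j], i)
        union(i, i)
    cluster_map: dict[int, list[int]] = {}
    for j in range(n):
        root = find(membership[j]) if membership[j] != -1 else j
        cluster_map.setdefault(root, []).append(j)
    ordered_roots = sorted(cluster_map, key=lambda r: min(cluster_map[r]))

    clusters: list[list[str]] = []
    reps: list[str] = []
    for root in ordered_roots:
        members = sorted(graph.nodes[j] for j in cluster_map[root])
        clusters.append(members)
        reps.append(min(members, key=lambda m: (-graph.degree(m), m)))
    return ClusterSet(
        clusters=clusters,
        representatives=reps,
        method="mcl",
        params_used={"inflation": inflation, "prune_below": prune_below},
    )


def greedy_identity_cluster(
    records: Sequence[SequenceRecord],
    threshold_pct: float = 90.0,
    prefilter_k: int = 5,
    params: AlignParams = AlignParams(),
) -> ClusterSet:
    """Greedy incremental clustering at a percent-identity threshold.

    Records are processed longest-first (ties by id).  Each record joins
    the first existing cluster whose representative aligns at or above the
    threshold; otherwise it founds a new cluster with itself as
    representative.  Candidate representatives sharing no length-
    ``prefilter_k`` word with the record are skipped without aligning.
    Deterministic and order-invariant given the internal sort.
    """
    if not records:
        raise ValueError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    rep_records: list[SequenceRecord] = []
    rep_words: list[set[str]] = []
    clusters: list[list[str]] = []

    def words(seq: str) -> set[str]:
        if len(seq) < prefilter_k:
            return set()
        return {
            seq[i : i + prefilter_k]
            for i in range(len(seq) - prefilter_k + 1)
            if "X" not in seq[i : i + prefilter_k]
        }

    for rec in ordered:
        w = words(rec.sequence)
        placed = False
        for ci, rep in enumerate(rep_records):
            if not (w & rep_words[ci]):
                continue
            if align_identity(rec.sequence, rep.sequence, params) >= threshold_pct:
                clusters[ci].append(rec.id)
                placed = True
                break
        if not placed:
            rep_records.append(rec)
            rep_words.append(w)
            clusters.append([rec.id])
    return ClusterSet(
        clusters=clusters,
        representatives=[r.id for r in rep_records],
        method="greedy_identity",
        params_used={"threshold_pct": threshold_pct, "prefilter_k": prefilter_k},
    )


def restore_characterised(
    clusters: ClusterSet, characterised_ids: Iterable[str]
) -> list[str]:
    """Representatives plus characterised accessions, deduplicated.

    Clustering demotes characterised members that are not representatives;
    the audit adds them back so the closest-characterised search always
    sees the full evidence set.  Stable order: representatives first.
    """
    members = {m for c in clusters.clusters for m in c}
    out = list(clusters.representatives)
    present = set(out)
    for acc in characterised_ids:
        if acc not in members:
            warnings.warn(f"characterised id {acc!r} absent from clustering")
        if acc not in present:
            out.append(acc)
            present.add(acc)
    return out


def write_clusters_tsv(clusters: ClusterSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("cluster_index\tmember_id\tis_representative\n")
        for i, cluster in enumerate(clusters.clusters):
            rep = clusters.representatives[i]
            for member in cluster:
                fh.write(f"{i}\t{member}\t{int(member == rep)}\n")


def write_clusters_mcl(clusters: ClusterSet, path: str | Path) -> None:
    """One cluster per line, members tab-separated (mcl output style)."""
    with Path(path).open("w") as fh:
        for cluster in clusters.clusters:
            fh.write("\t".join(cluster) + "\n")
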