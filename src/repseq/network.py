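"""BCR sequence networks and clonality measures.

A repertoire network has one vertex per unique nucleotide sequence,
weighted by read count, with an edge between vertices at edit (Levenshtein)
distance exactly 1 — a single substitution, insertion or deletion, so
homopolymer-indel artefacts stay connected to their parent vertex. Clusters
are the connected components and are interpreted as clonal lineages.

Clonality measures: the vertex Gini index (unevenness of vertex read
counts — overall clonality), the cluster Gini index (unevenness of cluster
sizes — lineage/mutational structure) and the maximum cluster size (the
percentage of reads in the largest cluster — degree of clonal expansion).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np

from .processing import AnnotatedSequence


@dataclass
class RepertoireNetwork:
    vertices: dict[str, int]  # unique sequence -> read count
    edges: set[frozenset[str]]
    clusters: list[set[str]]
    total_reads: int


@dataclass(frozen=True)
class DiversitySummary:
    vertex_gini: float
    cluster_gini: float
    max_cluster_pct: float
    n_vertices: int
    n_clusters: int


def gini_index(sizes) -> float:
    """Gini index of a list of positive sizes, in the mean-absolute-
    difference form G = sum_ij |x_i - x_j| / (2 n^2 mean); 0 for perfectly
    even lists and single elements."""
    x = np.asarray(list(sizes), dtype=float)
    if x.size == 0:
        raise ValueError("gini_index of an empty list")
    if np.any(x <= 0):
        raise ValueError("sizes must be positive")
    if x.size == 1:
        return 0.0
    xs = np.sort(x)
    n = xs.size
    total = xs.sum()
    # equivalent sorted form of the mean-absolute-difference definition
    return float((2.0 * np.sum(np.arange(1, n + 1) * xs) - (n + 1) * total) / (n * total))


def _distance_is_one(a: str, b: str) -> bool:
    if a == b:
        return False
    return edlib.align(a, b, mode="NW", task="distance", k=1)["editDistance"] == 1


def _edge_candidates(seqs: list[str]) -> set[tuple[int, int]]:
    """Candidate index pairs at edit distance <= 1 via deletion-neighborhood
    hashing: two sequences are at distance 1 only if one equals a single-
    deletion variant of the other (indel) or they share a single-deletion
    variant (substitution). Buckets are keyed by hash; candidates are
    verified exactly by the caller."""
    buckets: dict[int, list[int]] = defaultdict(list)
    for idx, s in enumerate(seqs):
        buckets[hash(s)].append(idx)
        for pos in range(len(s)):
            buckets[hash(s[:pos] + s[pos + 1:])].append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        uniq = sorted(set(members))
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                pairs.add((uniq[i], uniq[j]))
    return pairs


def build_network(annotated: list[AnnotatedSequence]) -> RepertoireNetwork:
    """Deduplicate sequences (summing read counts), connect vertices at edit
    distance exactly 1, and partition into connected components. An empty
    input yields an empty network."""
    counts: dict[str, int] = {}
    for ann in annotated:
        if not ann.sequence:
            raise ValueError(f"{ann.read_id}: empty sequence")
        counts[ann.sequence] = counts.get(ann.sequence, 0) + ann.read_count

    seqs = sorted(counts)  # deterministic vertex order
    graph = nx.Graph()
    graph.add_nodes_from(seqs)
    edges: set[frozenset[str]] = set()
    for i, j in sorted(_edge_candidates(seqs)):
        if _distance_is_one(seqs[i], seqs[j]):
            edges.add(frozenset((seqs[i], seqs[j])))
            graph.add_edge(seqs[i], seqs[j])
    clusters = [set(c) for c in nx.connected_components(graph)]
    clusters.sort(key=lambda c: (-sum(counts[s] for s in c), min(c)))
    return RepertoireNetwork(
        vertices=counts,
        edges=edges,
        clusters=clusters,
        total_reads=sum(counts.values()),
    )


def diversity_summary(
    network: RepertoireNetwork, cluster_weight: str = "reads"
) -> DiversitySummary:
    """Summarise a network. ``cluster_weight`` selects what "cluster size"
    means for the cluster Gini: total read mass per cluster (default) or the
    number of vertices per cluster."""
    if not network.vertices:
        return DiversitySummary(0.0, 0.0, 0.0, 0, 0)
    if cluster_weight not in ("reads", "vertices"):
        raise ValueError("cluster_weight must be 'reads' or 'vertices'")
    vertex_counts = list(network.vertices.values())
    if cluster_weight == "reads":
        cluster_sizes = [sum(network.vertices[s] for s in c) for c in network.clusters]
    else:
        cluster_sizes = [len(c) for c in network.clusters]
    cluster_reads = [sum(network.vertices[s] for s in c) for c in network.clusters]
    return DiversitySummary(
        vertex_gini=gini_index(vertex_counts),
        cluster_gini=gini_index(cluster_sizes),
        max_cluster_pct=100.0 * max(cluster_reads) / network.total_reads,
        n_vertices=len(network.vertices),
        n_clusters=len(network.clusters),
    )


def export_edges(network: RepertoireNetwork) -> list[tuple[str, str]]:
    """Edge list as sorted (sequence, sequence) pairs, deterministic."""
    return sorted(tuple(sorted(e)) for e in network.edges)


def to_graph(network: RepertoireNetwork) -> nx.Graph:
    graph = nx.Graph()
    for seq in sorted(network.vertices):
        graph.add_node(seq, read_count=network.vertices[seq])
    graph.add_edges_from(export_edges(network))
    return graph
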