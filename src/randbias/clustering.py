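"""PhenoGraph-style sub-classification of samples.

Samples are connected in a k-nearest-neighbor graph under Spearman
correlation distance; candidate edges (pairs appearing in either endpoint's
neighbor list) are weighted by the statistical surprise of their shared
neighbors — the upper-tail hypergeometric probability of the observed
overlap, transformed to ``-log10 p`` — and communities are found by Louvain
modularity maximization. The cluster count is data-driven; only k is chosen
(default 30, or n/3 for small cohorts) and the outcome is famously
insensitive to it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sps

from .containers import ExpressionMatrix
from .stats import hypergeometric_tail

logger = logging.getLogger("randbias")

__all__ = [
    "NeighborGraph",
    "ClusterPartition",
    "spearman_distance_matrix",
    "build_knn_graph",
    "weight_edges",
    "louvain",
    "cluster_dataset",
    "modularity",
]

WEIGHT_CAP = 300.0


@dataclass
class NeighborGraph:
    sample_ids: list[str]
    neighbors: np.ndarray  # (n, k) int indices, self excluded
    edges: list[tuple[int, int, float]]  # (i, j, weight) with i < j
    k: int


@dataclass
class ClusterPartition:
    sample_ids: list[str]
    labels: np.ndarray  # community id per sample, contiguous ints from 0
    modularity: float
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length must match sample_ids")


def spearman_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman correlation between sample columns."""
    ranks = sps.rankdata(values, axis=0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    return 1.0 - corr


def build_knn_graph(expr: ExpressionMatrix, k: int) -> NeighborGraph:
    """k nearest samples per sample under Spearman distance.

    Ties broken by ascending sample index; candidate edges are all pairs in
    either endpoint's neighbor list (weights filled in by
    :func:`weight_edges`).
    """
    n = expr.n_samples
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples ({n})")
    D = spearman_distance_matrix(expr.values)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    neighbors = order[:, :k]
    pairs: set[tuple[int, int]] = set()
    for i in range(n):
        for j in neighbors[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = [(i, j, 0.0) for i, j in sorted(pairs)]
    return NeighborGraph(list(expr.sample_ids), neighbors, edges, k)


def weight_edges(graph: NeighborGraph) -> NeighborGraph:
    """Weight candidate edges by shared-neighbor enrichment.

    For a pair (i, j): overlap of their neighbor sets excluding i and j, each
    drawn from a universe of n-2 other samples; weight is ``-log10`` of the
    hypergeometric upper tail (capped at 300). Pairs with zero overlap keep
    their edge only when they are mutual nearest neighbors.
    """
    n = len(graph.sample_ids)
    nbr_sets = [set(map(int, row)) for row in graph.neighbors]
    weighted: list[tuple[int, int, float]] = []
    for i, j, _ in graph.edges:
        si = nbr_sets[i] - {i, j}
        sj = nbr_sets[j] - {i, j}
        overlap = len(si & sj)
        mutual = (j in nbr_sets[i]) and (i in nbr_sets[j])
        if overlap == 0 and not mutual:
            continue
        p = hypergeometric_tail(overlap, len(si), len(sj), n - 2)
        w = min(-np.log10(max(p, 1e-300)), WEIGHT_CAP) if p < 1 else 0.0
        weighted.append((i, j, w))
    return NeighborGraph(graph.sample_ids, graph.neighbors, weighted, graph.k)


def _graph_to_nx(graph: NeighborGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(len(graph.sample_ids)))
    G.add_weighted_edges_from(graph.edges)
    return G


def modularity(graph: NeighborGraph, labels: np.ndarray) -> float:
    """Direct evaluation of Newman modularity Q for a labeling.

    Q = sum_c ( w_c / W - (d_c / 2W)^2 ) over communities, with W the total
    edge weight, w_c the within-community weight and d_c the community's
    weighted degree. Zero by convention for an edgeless (or zero-weight)
    graph.
    """
    labels = np.asarray(labels)
    W = sum(w for _, _, w in graph.edges)
    if W <= 0:
        return 0.0
    n_comm = labels.max() + 1
    w_in = np.zeros(n_comm)
    degree = np.zeros(len(labels))
    for i, j, w in graph.edges:
        degree[i] += w
        degree[j] += w
        if labels[i] == labels[j]:
            w_in[labels[i]] += w
    d_c = np.bincount(labels, weights=degree, minlength=n_comm)
    return float((w_in / W - (d_c / (2.0 * W)) ** 2).sum())


def louvain(graph: NeighborGraph, seed: int = 0) -> ClusterPartition:
    """Louvain community detection on the weighted graph (resolution 1).

    Node visit order is shuffled by ``seed``; the reported modularity is
    re-evaluated directly from the modularity formula on the stored graph.
    An edgeless / zero-weight graph yields singleton communities with Q = 0
    and a warning.
    """
    n = len(graph.sample_ids)
    total_w = sum(w for _, _, w in graph.edges)
    if not graph.edges or total_w <= 0:
        warnings.warn("graph has no positive-weight edges: singleton communities")
        return ClusterPartition(
            list(graph.sample_ids), np.arange(n), 0.0, graph.k, seed
        )
    G = _graph_to_nx(graph)
    comms = nx.community.louvain_communities(G, weight="weight", seed=seed)
    # deterministic label order: by smallest member index
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(comms):
        labels[list(members)] = cid
    return ClusterPartition(
        list(graph.sample_ids), labels, modularity(graph, labels), graph.k, seed
    )


def cluster_dataset(
    expr: ExpressionMatrix, k: int | None = None, seed: int = 0
) -> ClusterPartition:
    """Full sub-classification: kNN graph -> overlap weights -> Louvain."""
    if k is None:
        k = max(2, min(30, expr.n_samples // 3))
    graph = weight_edges(build_knn_graph(expr, k))
    return louvain(graph, seed=seed)
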