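"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: modularity comes from
networkx, Ward agglomeration is re-derived from the within-cluster
sum-of-squares definition, and AUC is the literal pairwise comparison.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def nx_modularity(graph: nx.Graph, groups: list[set[str]]) -> float:
    return nx.algorithms.community.modularity(graph, groups)


def best_first_merge_gain(graph: nx.Graph) -> float:
    """Max modularity over all single merges of two adjacent singleton groups."""
    base = [{n} for n in graph.nodes]
    best = -np.inf
    for u, v in graph.edges:
        groups = [g for g in base if g not in ({u}, {v})] + [{u, v}]
        best = max(best, nx_modularity(graph, groups))
    return best


def random_connected_graph(rng: np.random.Generator, n_max: int = 7) -> nx.Graph:
    """Random connected simple graph: random spanning tree plus extra edges."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"v{i}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    order = list(rng.permutation(n))
    for i in range(1, n):
        j = int(rng.integers(i))
        g.add_edge(nodes[order[i]], nodes[order[j]])
    p_extra = rng.uniform(0.0, 0.6)
    for i in range(n):
        for j in range(i + 1, n):
            if not g.has_edge(nodes[i], nodes[j]) and rng.random() < p_extra:
                g.add_edge(nodes[i], nodes[j])
    return g


def brute_force_ward_partitions(X: np.ndarray) -> dict[int, set[frozenset[int]]]:
    """Minimum-variance agglomeration from the SSE definition.

    Repeatedly merges the pair of clusters whose union increases the total
    within-cluster sum of squares the least; returns the partition (as sets of
    frozen sample-index sets) at every cluster count.
    """
    X = np.asarray(X, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(X.shape[0])]

    def sse(idx: list[int]) -> float:
        pts = X[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    partitions = {len(clusters): {frozenset(c) for c in clusters}}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            cost = sse(clusters[a] + clusters[b]) - sse(clusters[a]) - sse(clusters[b])
            if best is None or cost < best[0]:
                best = (cost, a, b)
        _c, a, b = best
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        partitions[len(clusters)] = {frozenset(c) for c in clusters}
    return partitions


def pairwise_auc(scores, labels) -> float:
    """Literal P(score_pos > score_neg) with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = scores[y]
    neg = scores[~y]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
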