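"""Dimension co-occurrence network and its cluster structure.

The label sets define a bipartite graph (words on one side, the eight
dimensions as parent nodes on the other). Projecting it onto the
dimensions yields, per dimension pair, the number of shared words and the
Jaccard index. Average-linkage hierarchical clustering on 1 − Jaccard
recovers the coarse grouping of dimensions that tend to characterise the
same words (e.g. an inner-experience group — introspection, mental
states, social, moral — versus a magnitude/knowledge group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .classification import DimensionLabelSet
from .variables import SEMANTIC_DIMENSIONS

__all__ = [
    "CooccurrenceNetwork",
    "bipartite_edges",
    "cooccurrence",
    "cluster_dimensions",
]


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Pairwise shared-word counts and Jaccard indices over the dimensions."""

    dims: tuple[str, ...]
    counts: Mapping[str, int]                      # words per dimension
    shared: Mapping[tuple[str, str], int]          # per unordered pair
    jaccard: Mapping[tuple[str, str], float]
    n_words: int

    def pair(self, a: str, b: str) -> tuple[str, str]:
        """Canonical (dimension-order) key for an unordered pair."""
        ia, ib = self.dims.index(a), self.dims.index(b)
        return (a, b) if ia < ib else (b, a)

    def to_graph(self) -> nx.Graph:
        """networkx projection graph with shared/jaccard edge attributes."""
        g = nx.Graph()
        for d in self.dims:
            g.add_node(d, count=int(self.counts[d]))
        for (a, b), s in self.shared.items():
            if s > 0:
                g.add_edge(a, b, shared=int(s), jaccard=float(self.jaccard[(a, b)]))
        return g


def bipartite_edges(labels: Sequence[DimensionLabelSet]
                    ) -> list[tuple[str, str]]:
    """Word -> parent-dimension edges; one per (word, dim in dims)."""
    edges = []
    for lab in labels:
        for d in SEMANTIC_DIMENSIONS:
            if d in lab.dims:
                edges.append((lab.word, d))
    return edges


def cooccurrence(labels: Sequence[DimensionLabelSet]) -> CooccurrenceNetwork:
    """Project the bipartite graph onto the dimensions.

    shared(d1, d2) = number of words labelled with both;
    Jaccard(d1, d2) = shared / number labelled with either (0, with a
    warning, when a dimension labels no word at all).
    """
    dims = SEMANTIC_DIMENSIONS
    members: dict[str, set[str]] = {d: set() for d in dims}
    for lab in labels:
        for d in lab.dims:
            members[d].add(lab.word)
    empty = [d for d in dims if not members[d]]
    if empty:
        warnings.warn(f"dimensions with zero labelled words: {empty}")
    counts = {d: len(members[d]) for d in dims}
    shared: dict[tuple[str, str], int] = {}
    jaccard: dict[tuple[str, str], float] = {}
    for a, b in combinations(dims, 2):
        inter = len(members[a] & members[b])
        union = len(members[a] | members[b])
        shared[(a, b)] = inter
        jaccard[(a, b)] = inter / union if union else 0.0
    return CooccurrenceNetwork(
        dims=tuple(dims), counts=counts, shared=shared, jaccard=jaccard,
        n_words=len({lab.word for lab in labels}),
    )


def cluster_dimensions(network: CooccurrenceNetwork, k: int = 2
                       ) -> list[tuple[str, ...]]:
    """Cut an average-linkage tree on distance 1 − Jaccard at k clusters.

    Deterministic: dimensions are ordered lexicographically before the
    distance matrix is built, so ties break reproducibly. Returns the
    partition as tuples of dimension names (canonical order within each
    cluster), sorted by each cluster's first dimension.
    """
    if k > len(network.dims):
        raise ValueError(
            f"cannot form {k} clusters from {len(network.dims)} dimensions")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(network.dims)  # lexicographic for deterministic ties
    dist = np.zeros((len(order), len(order)))
    for i, a in enumerate(order):
        for j in range(i + 1, len(order)):
            d = 1.0 - network.jaccard[network.pair(a, order[j])]
            dist[i, j] = dist[j, i] = d
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=k, criterion="maxclust")
    clusters: dict[int, list[str]] = {}
    for dim, c in zip(order, assignment):
        clusters.setdefault(int(c), []).append(dim)
    parts = [tuple(d for d in SEMANTIC_DIMENSIONS if d in set(mem))
             for mem in clusters.values()]
    return sorted(parts, key=lambda part: SEMANTIC_DIMENSIONS.index(part[0]))
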