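"""Shared fixtures and independent oracles.

The oracles here (brute-force bijection isomorphism, networkx subgraph
monomorphism matching, exhaustive-subset maximum independent set) share no
code with the package's canonical labeling, census or MIS routines, so they
can serve as ground truth on small instances.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from mdet import Graph


def make_graph(n: int, edges) -> Graph:
    return Graph(n, edges)


@pytest.fixture
def triangle() -> Graph:
    return Graph(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3() -> Graph:
    return Graph(3, [(0, 1), (1, 2)])


@pytest.fixture
def path4() -> Graph:
    return Graph(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def star4() -> Graph:
    return Graph(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def k4() -> Graph:
    return Graph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


def random_connected_graph(k: int, rng: random.Random, p: float = 0.5) -> Graph:
    """Seeded random connected graph on k vertices."""
    while True:
        edges = [
            (i, j) for i in range(k) for j in range(i + 1, k) if rng.random() < p
        ]
        g = Graph(k, edges)
        if g.is_connected():
            return g


def to_networkx(g: Graph) -> nx.Graph:
    ng = nx.Graph()
    ng.add_nodes_from(range(g.n))
    ng.add_edges_from(g.edges)
    return ng


def brute_force_isomorphic(g1: Graph, g2: Graph) -> bool:
    """All-bijections isomorphism search."""
    if g1.n != g2.n or g1.n_edges != g2.n_edges:
        return False
    for perm in itertools.permutations(range(g1.n)):
        if all(g2.has_edge(perm[u], perm[v]) for u, v in g1.edges):
            return True
    return False


def oracle_occurrences(g: Graph, pattern: Graph) -> set[frozenset[tuple[int, int]]]:
    """All occurrences of ``pattern`` in ``g`` as image edge sets, via
    networkx subgraph monomorphism (non-induced), one per vertex-set/edge-set
    occurrence."""
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        to_networkx(g), to_networkx(pattern)
    )
    occ: set[frozenset[tuple[int, int]]] = set()
    for mapping in matcher.subgraph_monomorphisms_iter():
        inv = {pv: gv for gv, pv in mapping.items()}
        occ.add(
            frozenset(
                (min(inv[a], inv[b]), max(inv[a], inv[b])) for a, b in pattern.edges
            )
        )
    return occ


def brute_force_mis_size(conflicts: list[set[int]]) -> int:
    """Exhaustive maximum independent set size over all subsets."""
    n = len(conflicts)
    best = 0
    for mask in range(1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if len(members) <= best:
            continue
        if all(j not in conflicts[i] for i in members for j in members if i < j):
            best = len(members)
    return best
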