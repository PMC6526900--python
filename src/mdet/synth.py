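"""Deterministic synthetic network generators for exercising the pipeline.

These are the test-surface inputs: seeded Erdős–Rényi graphs, graphs with a
known number of vertex-disjoint planted pattern copies (so the pattern's
edge-disjoint frequency has a constructive lower bound), and an exhaustive
brute-force enumeration of small connected graphs used as an isomorphism-
class oracle.  The brute-force enumeration deliberately shares no code with
the expansion tree so the two can check each other.
"""

from __future__ import annotations

import random

from .canonical import canonical_string_of_masks
from .graph import Graph


def erdos_renyi(n: int, p: float, seed: int) -> Graph:
    """G(n, p) with a seeded RNG; simple and undirected."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = random.Random(seed)
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return Graph(n, edges)


def planted_motif_graph(
    pattern: Graph,
    copies: int,
    noise_n: int = 0,
    noise_p: float = 0.0,
    seed: int = 0,
) -> Graph:
    """``copies`` vertex-disjoint copies of ``pattern`` plus an Erdős–Rényi
    noise block and sparse random bridges.

    The planted copies are pairwise vertex-disjoint, so the pattern's F2
    frequency is at least ``copies`` by construction.  Each bridge joins one
    planted copy to a distinct noise vertex (at most one bridge endpoint per
    noise vertex), which keeps bridges from completing new clique-like
    pattern copies across blocks.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = random.Random(seed)
    kp = pattern.n
    n = copies * kp + noise_n
    labels = [f"m{c}_{v}" for c in range(copies) for v in range(kp)]
    labels += [f"n{t}" for t in range(noise_n)]
    edges: list[tuple[int, int]] = []
    for c in range(copies):
        off = c * kp
        edges.extend((off + u, off + v) for u, v in pattern.edges)
    base = copies * kp
    for i in range(noise_n):
        for j in range(i + 1, noise_n):
            if rng.random() < noise_p:
                edges.append((base + i, base + j))
    if noise_n > 0:
        bridge_targets = rng.sample(range(noise_n), min(copies, noise_n))
        for c, t in enumerate(bridge_targets):
            u = c * kp + rng.randrange(kp)
            edges.append((u, base + t))
    return Graph(n, edges, labels)


def all_small_graphs(k: int) -> list[Graph]:
    """Every connected graph on ``k`` vertices, once per isomorphism class.

    Independent brute force: enumerate all edge subsets of K_k, keep the
    connected ones, deduplicate by canonical string.  Only labelings whose
    degree vector is already non-increasing are examined (every class has
    one), which prunes the enumeration without losing classes.  Returned
    graphs are in canonical vertex order, sorted by (edge count, canonical
    string).
    """
    if not 3 <= k <= 7:
        raise ValueError("supported for 3 <= k <= 7")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    ne = len(pairs)
    vmask = [0] * k
    for e, (a, b) in enumerate(pairs):
        vmask[a] |= 1 << e
        vmask[b] |= 1 << e
    found: dict[str, Graph] = {}
    min_edges = k - 1
    for m in range(1 << ne):
        if m.bit_count() < min_edges:
            continue
        degs = [(m & vmask[v]).bit_count() for v in range(k)]
        ok = True
        prev = k
        for d in degs:
            if d == 0 or d > prev:
                ok = False
                break
            prev = d
        if not ok:
            continue
        # adjacency masks + connectivity
        adj = [0] * k
        mm = m
        while mm:
            e = (mm & -mm).bit_length() - 1
            mm &= mm - 1
            a, b = pairs[e]
            adj[a] |= 1 << b
            adj[b] |= 1 << a
        seen = 1
        frontier = 1
        while frontier:
            nxt = 0
            while frontier:
                v = (frontier & -frontier).bit_length() - 1
                frontier &= frontier - 1
                nxt |= adj[v]
            frontier = nxt & ~seen
            seen |= frontier
        if seen.bit_count() != k:
            continue
        canon_string, perm = canonical_string_of_masks(k, adj)
        if canon_string in found:
            continue
        edges = [(perm[a], perm[b]) for e2, (a, b) in enumerate(pairs) if m >> e2 & 1]
        edges = [(min(u, v), max(u, v)) for u, v in edges]
        found[canon_string] = Graph(k, edges)
    return [
        found[s]
        for s in sorted(found, key=lambda s: (found[s].n_edges, s))
    ]
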