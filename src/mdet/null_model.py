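"""Degree-preserving randomization by edge switching.

The null model against which motif significance is measured: repeated
two-edge swaps (a,b),(c,d) -> (a,d),(c,b) that keep every vertex's degree
exactly, rejecting proposals that would create self-loops or duplicate
edges.  Attempts, not successful swaps, are counted; endpoints are oriented
uniformly at random per proposal so the stored edge orientation carries no
bias.  Connectivity is not enforced.
"""

from __future__ import annotations

import random

from .graph import Graph


def switch_randomize(g: Graph, n_swap_attempts: int, rng_seed: int) -> Graph:
    """One randomized copy of ``g`` with the per-vertex degree sequence
    preserved; reproducible from ``rng_seed``.  Graphs with fewer than two
    edges are returned unchanged (no swap is possible)."""
    if n_swap_attempts < 0:
        raise ValueError("n_swap_attempts must be >= 0")
    edges = sorted(g.edges)
    m = len(edges)
    if m < 2:
        return g.copy()
    rng = random.Random(rng_seed)
    adjset = [set(s) for s in g._adjset]
    for _ in range(n_swap_attempts):
        i = rng.randrange(m)
        j = rng.randrange(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            a, b = b, a
        if rng.random() < 0.5:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if d in adjset[a] or b in adjset[c]:
            continue
        adjset[a].discard(b)
        adjset[b].discard(a)
        adjset[c].discard(d)
        adjset[d].discard(c)
        adjset[a].add(d)
        adjset[d].add(a)
        adjset[c].add(b)
        adjset[b].add(c)
        edges[i] = (a, d) if a < d else (d, a)
        edges[j] = (c, b) if c < b else (b, c)
    return Graph(g.n, edges, g.labels)


def null_ensemble(g: Graph, N: int, q: float, seed: int) -> list[Graph]:
    """``N`` independent degree-preserving randomizations of ``g``, each
    using ``q * |E|`` swap attempts; replicate seeds derive deterministically
    from ``seed``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    attempts = int(round(q * g.n_edges))
    rng = random.Random(seed)
    seeds = [rng.randrange(2**31) for _ in range(N)]
    return [switch_randomize(g, attempts, s) for s in seeds]
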