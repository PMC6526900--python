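"""Canonical labeling of small graphs and isomorphism by string equality.

A pattern's canonical form is the vertex ordering whose adjacency bit string
is lexicographically smallest, so two small graphs are isomorphic exactly when
their canonical strings are equal.  The search places vertices one position at
a time: the bits connecting the new vertex to the already-placed prefix form a
fixed-length chunk, so greedy chunk minimisation with branching on ties is an
exact lexicographic minimisation.  Interchangeable (twin) candidates are
collapsed, which keeps highly symmetric graphs (cliques, complete bipartite
graphs) from exploding the branch count.

``canon_string`` is emitted as the row-major upper triangle of the canonically
ordered adjacency matrix: ``k(k-1)/2`` characters of '0'/'1'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .graph import Graph

#: Invocation counter for ``canonical_form``.  The census is designed to never
#: canonicalise during embedding propagation; tests assert this stays flat
#: across census expansion phases.
CANONICAL_CALLS = 0

_MAX_K = 15

# Cache keyed on the labeled adjacency (n, upper-triangle bitmask): identical
# labelings recur when the same candidate pattern is rebuilt across networks.
_cache: dict[tuple[int, int], tuple[str, tuple[int, ...]]] = {}


@dataclass(frozen=True)
class CanonicalForm:
    """Canonical string plus the permutation that realises it.

    ``perm[v]`` is the canonical position of input vertex position ``v``.
    """

    canon_string: str
    perm: tuple[int, ...]


def _min_order(n: int, adj: list[int]) -> list[int]:
    """Vertex ordering minimising the placement-order adjacency bit sequence.

    ``adj`` holds per-vertex neighbor bitmasks.  Returns ``order`` with
    ``order[p]`` = input vertex at canonical position ``p``; deterministic
    (first optimum under ascending-id candidate iteration).
    """
    if n == 1:
        return [0]
    best_chunks: list[int] | None = None
    best_order: list[int] | None = None
    order = [0] * n
    chunks = [0] * n

    def rec(pos: int, used: int, tied: bool) -> None:
        # `tied`: chunks[0..pos-1] equal best_chunks[0..pos-1] and best exists.
        nonlocal best_chunks, best_order
        # chunk for candidate v: adjacency bits to order[0..pos-1], order[0]
        # most significant, so integer comparison is bit-sequence comparison
        mc = -1
        cands: list[int] = []
        for v in range(n):
            if used >> v & 1:
                continue
            av = adj[v]
            c = 0
            for i in range(pos):
                c = (c << 1) | (av >> order[i] & 1)
            if mc < 0 or c < mc:
                mc = c
                cands = [v]
            elif c == mc:
                cands.append(v)
        if tied and best_chunks is not None:
            b = best_chunks[pos]
            if mc > b:
                return
            child_tied = mc == b
        else:
            child_tied = False
        chunks[pos] = mc
        # collapse twins: swapping two vertices with identical adjacency
        # (ignoring their mutual bit) is an automorphism, so tied twins
        # lead to identical subtrees
        reps: list[int] = []
        for v in cands:
            av = adj[v]
            bv = 1 << v
            for r in reps:
                if (av ^ adj[r]) & ~bv & ~(1 << r) == 0:
                    break
            else:
                reps.append(v)
        if pos == n - 1:
            if not child_tied:
                order[pos] = reps[0]
                best_chunks = chunks.copy()
                best_order = order.copy()
            # tied completion reproduces the current best exactly: keep the
            # first-found order for a deterministic permutation
            return
        for v in reps:
            order[pos] = v
            rec(pos + 1, used | (1 << v), child_tied)
            # after the first subtree, best exists and shares our prefix
            # (any replacement happened below this node)
            child_tied = True

    rec(0, 0, False)
    assert best_order is not None
    return best_order


def canonical_form(pattern: Graph) -> CanonicalForm:
    """Canonical form of a small connected pattern graph (2 <= k <= 15)."""
    global CANONICAL_CALLS
    CANONICAL_CALLS += 1
    k = pattern.n
    if not 2 <= k <= _MAX_K:
        raise ValueError(f"pattern size {k} outside supported range 2..{_MAX_K}")
    if not pattern.is_connected():
        raise ValueError("pattern must be connected")
    bits = 0
    for u, v in pattern.edges:
        bits |= 1 << (u * _MAX_K + v)
    key = (k, bits)
    hit = _cache.get(key)
    if hit is not None:
        return CanonicalForm(hit[0], hit[1])
    adj = pattern.adjacency_masks()
    order = _min_order(k, adj)
    perm = [0] * k
    for p, v in enumerate(order):
        perm[v] = p
    chars = []
    for p in range(k):
        ap = adj[order[p]]
        for q in range(p + 1, k):
            chars.append("1" if ap >> order[q] & 1 else "0")
    canon_string = "".join(chars)
    tperm = tuple(perm)
    if len(_cache) < 1_000_000:
        _cache[key] = (canon_string, tperm)
    return CanonicalForm(canon_string, tperm)


def canonical_string_of_masks(n: int, adj: list[int]) -> tuple[str, tuple[int, ...]]:
    """Canonical string and perm straight from neighbor bitmasks.

    Fast path used by the expansion-tree builder, bypassing Graph
    construction and the connectivity check (candidates are connected by
    construction).  Counts as a canonicalisation.
    """
    global CANONICAL_CALLS
    CANONICAL_CALLS += 1
    bits = 0
    for v in range(n):
        av = adj[v] >> (v + 1)
        u = v + 1
        while av:
            if av & 1:
                bits |= 1 << (v * _MAX_K + u)
            av >>= 1
            u += 1
    key = (n, bits)
    hit = _cache.get(key)
    if hit is not None:
        return hit
    order = _min_order(n, adj)
    perm = [0] * n
    for p, v in enumerate(order):
        perm[v] = p
    chars = []
    for p in range(n):
        ap = adj[order[p]]
        for q in range(p + 1, n):
            chars.append("1" if ap >> order[q] & 1 else "0")
    result = ("".join(chars), tuple(perm))
    if len(_cache) < 1_000_000:
        _cache[key] = result
    return result


def is_isomorphic(g1: Graph, g2: Graph) -> bool:
    """Isomorphism of two small connected graphs via canonical strings."""
    if g1.n != g2.n or g1.n_edges != g2.n_edges:
        return False
    from .graph import degree_sequence

    if degree_sequence(g1) != degree_sequence(g2):
        return False
    return canonical_form(g1).canon_string == canonical_form(g2).canon_string


def map_to_canonical(
    embedding_vertices: Sequence[int], perm: Sequence[int]
) -> list[int]:
    """Reorder an embedding so position ``i`` holds the vertex sent to
    canonical position ``i`` by ``perm``.  Pure reordering."""
    if len(embedding_vertices) != len(perm):
        raise ValueError(
            f"length mismatch: {len(embedding_vertices)} vertices vs "
            f"{len(perm)}-entry permutation"
        )
    out = [0] * len(perm)
    for pos, vtx in enumerate(embedding_vertices):
        out[perm[pos]] = vtx
    return out
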