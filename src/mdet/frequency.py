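"""F2 (edge-disjoint) frequency of a pattern via a maximum independent set.

Two embeddings conflict when their image edge sets in the target network
intersect; the F2 frequency is the size of a large independent set of this
conflict graph.  The MIS is computed exactly (branch and bound) when the
instance is small and by a deterministic min-conflict-degree greedy heuristic
above that, since maximum independent set is NP-hard.  F2 satisfies downward
closure (a sub-pattern is at least as frequent as its super-pattern), which
is what makes frequency-based pruning of the expansion tree sound.
"""

from __future__ import annotations

import heapq

from .census import EmbeddingSet, image_edges
from .tree import ETNode

#: Largest conflict-graph size solved exactly; above this the greedy
#: heuristic is used.
EXACT_MIS_LIMIT = 25


class ConflictGraph:
    """Conflict structure over an embedding list.

    ``conflicts[i]`` is the set of item indices whose image edge sets
    intersect item ``i``'s.  Symmetric, no self-conflicts.
    """

    def __init__(self, items: list[tuple[int, ...]], conflicts: list[set[int]]):
        self.items = items
        self.conflicts = conflicts

    @property
    def n(self) -> int:
        return len(self.items)


def build_conflict_graph(es: EmbeddingSet, pattern: ETNode) -> ConflictGraph:
    """Conflict (i, j) iff the two embeddings share a target edge."""
    items = list(es.embeddings)
    pat_edges = sorted(pattern.pattern.edges)
    conflicts: list[set[int]] = [set() for _ in items]
    by_edge: dict[tuple[int, int], list[int]] = {}
    for idx, emb in enumerate(items):
        for a, b in pat_edges:
            x, y = emb[a], emb[b]
            key = (x, y) if x < y else (y, x)
            bucket = by_edge.setdefault(key, [])
            for other in bucket:
                conflicts[idx].add(other)
                conflicts[other].add(idx)
            bucket.append(idx)
    return ConflictGraph(items, conflicts)


def _mis_exact(conflicts: list[set[int]]) -> list[int]:
    """Exact maximum independent set by branch and bound over bitmasks.

    Deterministic: fixed pivot rule (max degree, lowest index) and fixed
    branch order, so the first optimum found is reproducible.
    """
    n = len(conflicts)
    nbr = [0] * n
    for i, cs in enumerate(conflicts):
        for j in cs:
            nbr[i] |= 1 << j
    best_size = -1
    best_set = 0

    def rec(pool: int, cur: int, cur_size: int) -> None:
        nonlocal best_size, best_set
        if cur_size + pool.bit_count() <= best_size:
            return
        if pool == 0:
            if cur_size > best_size:
                best_size = cur_size
                best_set = cur
            return
        # absorb isolated / degree<=1 items greedily (always safe)
        p = pool
        while p:
            v = (p & -p).bit_length() - 1
            p &= p - 1
            dmask = nbr[v] & pool
            d = dmask.bit_count()
            if d == 0:
                pool &= ~(1 << v)
                cur |= 1 << v
                cur_size += 1
            elif d == 1:
                pool &= ~((1 << v) | dmask)
                cur |= 1 << v
                cur_size += 1
                p &= pool
        if pool == 0:
            rec(0, cur, cur_size)
            return
        if cur_size + pool.bit_count() <= best_size:
            return
        # pivot: max conflict degree within pool, lowest index on ties
        pivot = -1
        pivot_d = -1
        p = pool
        while p:
            v = (p & -p).bit_length() - 1
            p &= p - 1
            d = (nbr[v] & pool).bit_count()
            if d > pivot_d:
                pivot_d = d
                pivot = v
        rec(pool & ~((1 << pivot) | nbr[pivot]), cur | (1 << pivot), cur_size + 1)
        rec(pool & ~(1 << pivot), cur, cur_size)

    rec((1 << n) - 1, 0, 0)
    return [i for i in range(n) if best_set >> i & 1]


def _mis_greedy(items: list[tuple[int, ...]], conflicts: list[set[int]]) -> list[int]:
    """Deterministic greedy: repeatedly take the remaining item with the
    fewest remaining conflicts (ties by lexicographic vertex list, then
    index) and discard its neighbors."""
    n = len(items)
    alive = [True] * n
    deg = [len(c) for c in conflicts]
    heap = [(deg[i], items[i], i) for i in range(n)]
    heapq.heapify(heap)
    chosen: list[int] = []
    while heap:
        d, _, i = heapq.heappop(heap)
        if not alive[i]:
            continue
        if d != deg[i]:  # stale entry; reinsert with current degree
            heapq.heappush(heap, (deg[i], items[i], i))
            continue
        chosen.append(i)
        alive[i] = False
        for j in conflicts[i]:
            if alive[j]:
                alive[j] = False
                for l in conflicts[j]:
                    if alive[l]:
                        deg[l] -= 1
    return sorted(chosen)


def edge_disjoint_embeddings(
    es: EmbeddingSet, pattern: ETNode, exact_limit: int = EXACT_MIS_LIMIT
) -> EmbeddingSet:
    """An independent set of the conflict graph; its size is the F2 count.

    Exact maximum for instances up to ``exact_limit`` items, deterministic
    greedy above.
    """
    if len(es.embeddings) <= 1:
        return EmbeddingSet(pattern, list(es.embeddings), deduplicated=True)
    cg = build_conflict_graph(es, pattern)
    if cg.n <= exact_limit:
        keep = _mis_exact(cg.conflicts)
    else:
        keep = _mis_greedy(cg.items, cg.conflicts)
    return EmbeddingSet(pattern, [cg.items[i] for i in keep], deduplicated=True)


def f2_frequency(
    es: EmbeddingSet, pattern: ETNode, exact_limit: int = EXACT_MIS_LIMIT
) -> int:
    """Edge-disjoint (F2) frequency of ``pattern`` given its embeddings."""
    return len(edge_disjoint_embeddings(es, pattern, exact_limit).embeddings)


def is_edge_disjoint(es: EmbeddingSet, pattern: ETNode) -> bool:
    """Validity check: no two embeddings share a target edge."""
    seen: set[tuple[int, int]] = set()
    for emb in es.embeddings:
        for e in image_edges(pattern, emb):
            if e in seen:
                return False
            seen.add(e)
    return True
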