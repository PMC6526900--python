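"""Embedding enumeration: the census phases of the motif search.

Occurrences of the root 3-vertex path are enumerated directly from the
adjacency structure; every deeper pattern's embeddings are derived from its
parent's via the stored attachment element and permutation — a vertex
addition extends each parent embedding through the neighbors of one image
vertex, an edge addition filters parent embeddings on the presence of one
closing edge.  No canonical form is ever computed during these expansion
phases; that work was done once when the tree node was created.

Embeddings are non-induced (extra target edges among the image vertices are
permitted) and each is stored aligned to the pattern's canonical vertex
order.  Two derivations reaching the same occurrence (same image edge set)
are collapsed to one representative, so frequencies count occurrences, not
traversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .graph import Graph
from .tree import (
    EDGE_LEVEL,
    ETNode,
    ExpansionTree,
    VERTEX_LEVEL,
    expand_by_edge,
    expand_by_vertex,
)

#: An embedding is an ordered tuple of distinct target-network vertex ids;
#: position i holds the image of canonical pattern vertex i.
Embedding = tuple[int, ...]


@dataclass
class EmbeddingSet:
    """Deduplicated embeddings of one pattern node."""

    pattern: ETNode
    embeddings: list[Embedding]
    deduplicated: bool = False

    def __len__(self) -> int:
        return len(self.embeddings)


def image_edges(pattern: ETNode, emb: Embedding) -> frozenset[tuple[int, int]]:
    """Target-network edges realising the pattern edges under ``emb``."""
    out = set()
    for a, b in pattern.pattern.edges:
        x, y = emb[a], emb[b]
        out.add((x, y) if x < y else (y, x))
    return frozenset(out)


def basic_tree_embeddings(g: Graph, tree: ExpansionTree) -> EmbeddingSet:
    """All occurrences of the root 3-path: one embedding ``<v, w, u>`` per
    center ``u`` and unordered neighbor pair ``{v, w}`` (v < w), remapped to
    the root's canonical order.  Count is sum over u of C(degree(u), 2)."""
    perm = getattr(tree, "root_basic_perm", (0, 1, 2))
    identity = tuple(perm) == (0, 1, 2)
    embs: list[Embedding] = []
    for u in range(g.n):
        nb = g.adj[u]
        d = len(nb)
        for ai in range(d):
            v = nb[ai]
            for bi in range(ai + 1, d):
                raw = (v, nb[bi], u)
                if identity:
                    embs.append(raw)
                else:
                    out = [0, 0, 0]
                    for pos in range(3):
                        out[perm[pos]] = raw[pos]
                    embs.append(tuple(out))
    return EmbeddingSet(tree.root, embs, deduplicated=True)


def _links_from(parent: ETNode, child: ETNode):
    links = [l for l in child.parent_links if l.parent is parent]
    if not links:
        raise ValueError("child is not linked to this parent in the tree")
    return links


def tree_census_step(
    tree: ExpansionTree,
    g: Graph,
    parent: ETNode,
    parent_embeddings: EmbeddingSet,
    child: ETNode,
) -> EmbeddingSet:
    """Vertex-addition expansion: extend each parent embedding through every
    neighbor of the attachment image, over all stored parent links, then
    remap to the child's canonical order and deduplicate by image edge set."""
    links = _links_from(parent, child)
    if child.level_kind != VERTEX_LEVEL:
        raise ValueError("child is not a vertex-addition node")
    kc = child.k_pattern
    child_edges = sorted(child.pattern.edges)
    seen: set[frozenset[tuple[int, int]]] = set()
    out: list[Embedding] = []
    adj = g.adj
    for link in links:
        u, _new = link.new_element
        mp = link.map
        for e in parent_embeddings.embeddings:
            a = e[u]
            in_e = set(e)
            for b in adj[a]:
                if b in in_e:
                    continue
                ne = [0] * kc
                for pos in range(kc - 1):
                    ne[mp[pos]] = e[pos]
                ne[mp[kc - 1]] = b
                key = frozenset(
                    (ne[x], ne[y]) if ne[x] < ne[y] else (ne[y], ne[x])
                    for x, y in child_edges
                )
                if key in seen:
                    continue
                seen.add(key)
                out.append(tuple(ne))
    return EmbeddingSet(child, out, deduplicated=True)


def graph_census_step(
    tree: ExpansionTree,
    g: Graph,
    parent: ETNode,
    parent_embeddings: EmbeddingSet,
    child: ETNode,
) -> EmbeddingSet:
    """Edge-addition expansion: keep the parent embeddings whose image
    contains the closing edge, remapped and deduplicated."""
    links = _links_from(parent, child)
    if child.level_kind != EDGE_LEVEL:
        raise ValueError("child is not an edge-addition node")
    kc = child.k_pattern
    child_edges = sorted(child.pattern.edges)
    seen: set[frozenset[tuple[int, int]]] = set()
    out: list[Embedding] = []
    for link in links:
        u, v = link.new_element
        mp = link.map
        for e in parent_embeddings.embeddings:
            if not g.has_edge(e[u], e[v]):
                continue
            ne = [0] * kc
            for pos in range(kc):
                ne[mp[pos]] = e[pos]
            key = frozenset(
                (ne[x], ne[y]) if ne[x] < ne[y] else (ne[y], ne[x])
                for x, y in child_edges
            )
            if key in seen:
                continue
            seen.add(key)
            out.append(tuple(ne))
    return EmbeddingSet(child, out, deduplicated=True)


@dataclass
class CensusRecord:
    """One pattern reached by the census, with its embeddings and F2 count."""

    node: ETNode
    f2: int
    disjoint: EmbeddingSet
    embeddings: EmbeddingSet = field(repr=False)


def run_census(
    tree: ExpansionTree,
    g: Graph,
    k: int,
    F: int,
    propagate: Literal["full", "disjoint"] = "disjoint",
    strict_threshold: bool = False,
    exact_mis_limit: int | None = None,
    keep_interior: bool = False,
) -> list[CensusRecord]:
    """Depth-first growth of the dynamic expansion tree over ``g``.

    Starting from the root's occurrence list, each node's edge-disjoint set
    is extracted; a node whose F2 count fails the frequency threshold is
    pruned (its subtree is never built), otherwise its children are created
    on demand and visited with embeddings propagated from this node.  By
    default children grow from the parent's edge-disjoint set; ``full``
    propagates the complete occurrence list instead (sensitivity checks and
    oracle comparisons).

    Returns one record per size-``k`` pattern reached (all visited patterns
    when ``keep_interior``).  The tree is built per motif size, so ``k``
    must equal its target size (edge additions happen at that size).
    """
    from .frequency import EXACT_MIS_LIMIT, edge_disjoint_embeddings

    if k != tree.k_target:
        raise ValueError(
            f"census size {k} must equal the tree's target size {tree.k_target}; "
            "build one tree per motif size"
        )
    limit = EXACT_MIS_LIMIT if exact_mis_limit is None else exact_mis_limit
    records: list[CensusRecord] = []

    def frequent(f2: int) -> bool:
        return f2 > F if strict_threshold else f2 >= F

    def visit(node: ETNode, embset: EmbeddingSet) -> None:
        disj = edge_disjoint_embeddings(embset, node, limit)
        f2 = len(disj.embeddings)
        if keep_interior or node.k_pattern == k:
            records.append(CensusRecord(node, f2, disj, embset))
        if not frequent(f2):
            return  # prune the subtree rooted here
        prop = disj if propagate == "disjoint" else embset
        if node.k_pattern < k:
            for child in expand_by_vertex(tree, node):
                visit(child, tree_census_step(tree, g, node, prop, child))
        elif not node.is_complete():
            for child in expand_by_edge(tree, node):
                visit(child, graph_census_step(tree, g, node, prop, child))

    visit(tree.root, basic_tree_embeddings(g, tree))
    return records


def dump_embeddings(records: Iterable[CensusRecord], g: Graph) -> str:
    """Per-pattern embedding dump: canon_string TAB comma-separated vertex
    labels, one embedding per line."""
    lines = []
    for rec in records:
        for emb in rec.disjoint.embeddings:
            lines.append(
                rec.node.canon_string + "\t" + ",".join(g.labels[v] for v in emb)
            )
    return "\n".join(lines) + ("\n" if lines else "")
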