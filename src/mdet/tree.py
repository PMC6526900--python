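"""The expansion tree of non-isomorphic patterns.

The tree is rooted at the 3-vertex path.  Vertex-addition levels grow the
pattern one pendant vertex at a time until it has ``k_target`` vertices (so
every node on these levels is a tree in the graph-theoretic sense); edge-
addition levels then add one edge per level until the complete graph is
reached.  Isomorphic candidate children are represented by a single node:
a duplicate generated from the *same* parent stores an extra parent link
(attachment element + permutation into the child's canonical order), while a
candidate isomorphic to a node created elsewhere in the tree is skipped
outright.  The stored permutations are what let the census remap embeddings
into canonical order without ever re-canonicalising a graph.

Built eagerly and exhaustively this is the static expansion tree whose node
count is (number of non-isomorphic trees on 3..k-1 vertices) + (number of
connected graphs on k vertices); built lazily under a frequency-pruning
census it is the dynamic expansion tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .canonical import CanonicalForm, canonical_string_of_masks
from .graph import Graph

VERTEX_LEVEL = "vertex"
EDGE_LEVEL = "edge"


@dataclass
class ParentLink:
    """One way a node's pattern extends a parent pattern.

    ``new_element`` is ``(u, v)`` in the parent-extended vertex ordering: for
    a vertex addition ``u`` is the attachment vertex in the parent and ``v``
    is the new vertex (index ``k_parent``); for an edge addition both are
    parent vertices.  ``map`` sends parent-extended positions to this node's
    canonical positions.
    """

    parent: "ETNode"
    new_element: tuple[int, int]
    map: tuple[int, ...]


@dataclass
class ETNode:
    """One non-isomorphic pattern in the expansion tree."""

    pattern: Graph  # stored in its own canonical vertex order
    canon: CanonicalForm
    level_kind: Literal["vertex", "edge"]
    k_pattern: int
    parent_links: list[ParentLink] = field(default_factory=list)
    children: list["ETNode"] = field(default_factory=list)
    _vertex_expanded: bool = False
    _edge_expanded: bool = False

    @property
    def canon_string(self) -> str:
        return self.canon.canon_string

    @property
    def n_edges(self) -> int:
        return self.pattern.n_edges

    def is_complete(self) -> bool:
        k = self.k_pattern
        return self.pattern.n_edges == k * (k - 1) // 2

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ETNode(k={self.k_pattern}, m={self.n_edges}, canon={self.canon_string!r})"


class ExpansionTree:
    """Expansion tree for motifs of up to ``k_target`` vertices."""

    def __init__(self, k_target: int, root: ETNode) -> None:
        self.k_target = k_target
        self.root = root
        self.registry: dict[str, ETNode] = {root.canon_string: root}


def _masks_from_graph(g: Graph) -> list[int]:
    return g.adjacency_masks()


def _graph_from_masks(n: int, adj: list[int]) -> Graph:
    edges = []
    for u in range(n):
        av = adj[u] >> (u + 1)
        v = u + 1
        while av:
            if av & 1:
                edges.append((u, v))
            av >>= 1
            v += 1
    return Graph(n, edges)


def make_root(k_target: int) -> ExpansionTree:
    """Tree containing only the root: the 3-vertex path in canonical order."""
    if not 3 <= k_target <= 15:
        raise ValueError(f"k_target must be in 3..15, got {k_target}")
    path3 = Graph(3, [(0, 1), (1, 2)])
    adj = path3.adjacency_masks()
    canon_string, perm = canonical_string_of_masks(3, adj)
    pattern = path3.relabel(perm)
    root = ETNode(
        pattern=pattern,
        canon=CanonicalForm(canon_string, tuple(range(3))),
        level_kind=VERTEX_LEVEL,
        k_pattern=3,
    )
    tree = ExpansionTree(k_target, root)
    # permutation sending the raw <v, w, u> basic-embedding order (edges at
    # positions (0,2) and (1,2)) into the root's canonical order
    vwu = Graph(3, [(0, 2), (1, 2)])
    vwu_string, vwu_perm = canonical_string_of_masks(3, vwu.adjacency_masks())
    assert vwu_string == canon_string
    tree.root_basic_perm = vwu_perm  # type: ignore[attr-defined]
    return tree


def _register_candidate(
    tree: ExpansionTree,
    node: ETNode,
    ext_n: int,
    ext_adj: list[int],
    new_element: tuple[int, int],
    level_kind: str,
) -> None:
    """Dedup policy shared by vertex and edge addition.

    Same-parent duplicate -> extra parent link on the existing child;
    elsewhere-in-tree duplicate -> skipped; otherwise a new child node.
    """
    canon_string, perm = canonical_string_of_masks(ext_n, ext_adj)
    for child in node.children:
        if child.canon_string == canon_string:
            child.parent_links.append(ParentLink(node, new_element, perm))
            return
    if canon_string in tree.registry:
        return
    raw = _graph_from_masks(ext_n, ext_adj)
    child = ETNode(
        pattern=raw.relabel(perm),
        canon=CanonicalForm(canon_string, tuple(range(ext_n))),
        level_kind=level_kind,  # type: ignore[arg-type]
        k_pattern=ext_n,
        parent_links=[ParentLink(node, new_element, perm)],
    )
    tree.registry[canon_string] = child
    node.children.append(child)


def expand_by_vertex(tree: ExpansionTree, node: ETNode) -> list[ETNode]:
    """Generate (or return already-generated) vertex-addition children.

    Each attachment vertex ``i`` of the parent yields the candidate
    parent + pendant vertex joined to ``i``; candidates are deduplicated per
    the expansion-tree policy.  Idempotent: a second call returns the
    existing children without re-generating links.
    """
    if node.level_kind != VERTEX_LEVEL:
        raise ValueError("vertex addition applies only to tree-pattern nodes")
    if node.k_pattern >= tree.k_target:
        raise ValueError(
            f"pattern already has {node.k_pattern} vertices (target {tree.k_target})"
        )
    if node._vertex_expanded:
        return list(node.children)
    k = node.k_pattern
    adj = _masks_from_graph(node.pattern)
    newbit = 1 << k
    for i in range(k):  # attachment vertices in canonical index order
        ext_adj = adj + [1 << i]
        ext_adj[i] = adj[i] | newbit
        _register_candidate(tree, node, k + 1, ext_adj, (i, k), VERTEX_LEVEL)
    node._vertex_expanded = True
    return list(node.children)


def expand_by_edge(tree: ExpansionTree, node: ETNode) -> list[ETNode]:
    """Generate (or return already-generated) edge-addition children.

    Absent vertex pairs are scanned row-major on the upper triangle; dedup
    policy as for vertex addition.  A complete-graph node is a leaf.
    """
    if node.k_pattern != tree.k_target:
        raise ValueError("edge addition applies only to size-k_target nodes")
    if node.is_complete():
        raise ValueError("complete graph has no absent vertex pairs")
    if node._edge_expanded:
        return list(node.children)
    k = node.k_pattern
    adj = _masks_from_graph(node.pattern)
    for i in range(k):
        for j in range(i + 1, k):
            if adj[i] >> j & 1:
                continue
            ext_adj = adj.copy()
            ext_adj[i] |= 1 << j
            ext_adj[j] |= 1 << i
            _register_candidate(tree, node, k, ext_adj, (i, j), EDGE_LEVEL)
    node._edge_expanded = True
    return list(node.children)


def build_static_tree(k_target: int) -> ExpansionTree:
    """Exhaustive breadth-first construction of the static expansion tree."""
    tree = make_root(k_target)
    frontier = [tree.root]
    while frontier and frontier[0].k_pattern < k_target:
        nxt: list[ETNode] = []
        for node in frontier:
            nxt.extend(expand_by_vertex(tree, node))
        frontier = nxt
    # frontier now holds the size-k_target trees; add edges level by level
    while frontier:
        nxt = []
        for node in frontier:
            if not node.is_complete():
                nxt.extend(expand_by_edge(tree, node))
        frontier = nxt
    return tree


def build_tree_levels(k_max: int) -> ExpansionTree:
    """Vertex-addition levels only: all non-isomorphic trees on 3..k_max
    vertices, one node each.  No edge-addition levels are built."""
    tree = make_root(k_max)
    frontier = [tree.root]
    while frontier and frontier[0].k_pattern < k_max:
        nxt: list[ETNode] = []
        for node in frontier:
            nxt.extend(expand_by_vertex(tree, node))
        frontier = nxt
    return tree


def count_nodes(tree: ExpansionTree) -> int:
    return len(tree.registry)


def dump_tree(tree: ExpansionTree) -> str:
    """One line per node: canon_string, pattern size, edge count and parent
    canon_strings — a debugging aid mirroring the node-count bookkeeping."""
    lines = []
    for canon_string, node in sorted(tree.registry.items(), key=lambda kv: (kv[1].k_pattern, kv[1].n_edges, kv[0])):
        parents = ",".join(sorted({l.parent.canon_string for l in node.parent_links})) or "-"
        lines.append(f"{canon_string}\t{node.k_pattern}\t{node.n_edges}\t{parents}")
    return "\n".join(lines) + "\n"
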