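"""Undirected simple graph container and readers for the formats the tool touches.

Vertices are dense 0-based integers internally; external string identifiers
(protein names, gene symbols, ...) are kept in a side table and used only when
reporting embeddings.  Graphs are unlabeled for pattern matching: motifs are
purely topological.
"""

from __future__ import annotations

from typing import Iterable, Sequence


class GraphParseError(ValueError):
    """Malformed line in a network file; the message names the line number."""


class Graph:
    """An undirected simple graph: no self-loops, no duplicate edges.

    Parameters
    ----------
    n_vertices:
        Number of vertices; internal ids are ``0 .. n_vertices-1``.
    edges:
        Iterable of vertex-id pairs.  Self-loops and duplicates are rejected.
    labels:
        Optional external identifiers, indexed by internal id.  Defaults to
        the decimal id.
    """

    __slots__ = ("n", "labels", "edges", "adj", "_adjset")

    def __init__(
        self,
        n_vertices: int,
        edges: Iterable[tuple[int, int]] = (),
        labels: Sequence[str] | None = None,
    ) -> None:
        if n_vertices < 0:
            raise ValueError("n_vertices must be non-negative")
        self.n = n_vertices
        if labels is None:
            self.labels = [str(i) for i in range(n_vertices)]
        else:
            if len(labels) != n_vertices:
                raise ValueError("labels length must equal n_vertices")
            self.labels = list(labels)
        self.edges: set[tuple[int, int]] = set()
        self._adjset: list[set[int]] = [set() for _ in range(n_vertices)]
        for u, v in edges:
            self._add_edge(u, v)
        self.adj: list[list[int]] = [sorted(s) for s in self._adjset]

    def _add_edge(self, u: int, v: int) -> None:
        if not (0 <= u < self.n and 0 <= v < self.n):
            raise ValueError(f"edge ({u}, {v}) out of range")
        if u == v:
            raise ValueError(f"self-loop at vertex {u}")
        if u > v:
            u, v = v, u
        if (u, v) in self.edges:
            raise ValueError(f"duplicate edge ({u}, {v})")
        self.edges.add((u, v))
        self._adjset[u].add(v)
        self._adjset[v].add(u)

    # -- queries ---------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: int, v: int) -> bool:
        return v in self._adjset[u]

    def degree(self, u: int) -> int:
        return len(self._adjset[u])

    def neighbors(self, u: int) -> list[int]:
        return self.adj[u]

    def is_connected(self) -> bool:
        if self.n == 0:
            return True
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in self._adjset[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n

    def adjacency_masks(self) -> list[int]:
        """Per-vertex neighbor bitmasks; only sensible for small graphs."""
        masks = [0] * self.n
        for u, v in self.edges:
            masks[u] |= 1 << v
            masks[v] |= 1 << u
        return masks

    def copy(self) -> "Graph":
        return Graph(self.n, self.edges, self.labels)

    def relabel(self, perm: Sequence[int]) -> "Graph":
        """Return the graph with vertex ``v`` moved to position ``perm[v]``."""
        if sorted(perm) != list(range(self.n)):
            raise ValueError("perm must be a permutation of the vertex ids")
        new_labels = [""] * self.n
        for v, p in enumerate(perm):
            new_labels[p] = self.labels[v]
        return Graph(self.n, [(perm[u], perm[v]) for u, v in self.edges], new_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.n == other.n and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.n, frozenset(self.edges)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(n={self.n}, m={self.n_edges})"


def _builder():
    """Shared label-interning state for the line-based readers."""
    labels: list[str] = []
    index: dict[str, int] = {}

    def vid(token: str) -> int:
        if token not in index:
            index[token] = len(labels)
            labels.append(token)
        return index[token]

    return labels, vid


def read_sif(path: str) -> Graph:
    """Read a Simple Interaction Format (SIF) file.

    Lines look like ``source relation target [target2 ...]``; the relation
    token is ignored.  A single-token line declares an isolated vertex.
    Duplicate edges and self-loops are silently dropped.  A two-token line
    (node + relation but no target) is malformed.
    """
    labels, vid = _builder()
    edges: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) == 1:
                vid(tokens[0])
                continue
            if len(tokens) == 2:
                raise GraphParseError(
                    f"{path}:{lineno}: SIF line has a relation but no target"
                )
            src = vid(tokens[0])
            for tok in tokens[2:]:
                dst = vid(tok)
                if src == dst:
                    continue
                edges.add((min(src, dst), max(src, dst)))
    return Graph(len(labels), edges, labels)


def read_edge_list(path: str) -> Graph:
    """Read a two-column whitespace edge list; ``#`` starts a comment line."""
    labels, vid = _builder()
    edges: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 tokens, found {len(tokens)}"
                )
            u, v = vid(tokens[0]), vid(tokens[1])
            if u == v:
                continue
            edges.add((min(u, v), max(u, v)))
    return Graph(len(labels), edges, labels)


def write_edge_list(g: Graph, path: str) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{g.labels[u]}\t{g.labels[v]}\n")


def write_sif(g: Graph, path: str, relation: str = "pp") -> None:
    """Write as SIF; isolated vertices become single-token lines."""
    with open(path, "w") as fh:
        touched = set()
        for u, v in sorted(g.edges):
            fh.write(f"{g.labels[u]}\t{relation}\t{g.labels[v]}\n")
            touched.add(u)
            touched.add(v)
        for v in range(g.n):
            if v not in touched:
                fh.write(f"{g.labels[v]}\n")


def degree_sequence(g: Graph) -> list[int]:
    """Multiset of vertex degrees, sorted descending."""
    return sorted((g.degree(v) for v in range(g.n)), reverse=True)
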