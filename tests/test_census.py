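"""Embedding enumeration and propagation."""

import random

import pytest

import mdet.canonical as canonical_mod
from mdet import (
    Graph,
    basic_tree_embeddings,
    build_static_tree,
    canonical_form,
    expand_by_vertex,
    graph_census_step,
    make_root,
    run_census,
    tree_census_step,
)
from mdet.census import image_edges
from conftest import oracle_occurrences, random_connected_graph


def _node(tree, edges, n):
    return tree.registry[canonical_form(Graph(n, edges)).canon_string]


class TestBasicTreeEmbeddings:
    @pytest.mark.parametrize(
        "edges, n, expected",
        [
            ([(0, 1), (0, 2), (0, 3)], 4, 3),  # K1,3: C(3,2)
            ([(0, 1), (1, 2), (0, 2)], 3, 3),  # triangle: each vertex a center
            ([(0, 1), (1, 2)], 3, 1),
        ],
    )
    def test_counts(self, edges, n, expected):
        es = basic_tree_embeddings(Graph(n, edges), make_root(3))
        assert len(es.embeddings) == expected

    def test_count_formula_and_distinctness(self):
        rng = random.Random(2)
        g = random_connected_graph(9, rng, p=0.4)
        es = basic_tree_embeddings(g, make_root(3))
        expected = sum(
            g.degree(u) * (g.degree(u) - 1) // 2 for u in range(g.n)
        )
        assert len(es.embeddings) == expected
        assert all(len(set(e)) == 3 for e in es.embeddings)

    def test_empty_graph(self):
        es = basic_tree_embeddings(Graph(0), make_root(3))
        assert es.embeddings == []


class TestTreeCensusStep:
    def test_path4_in_path4(self):
        tree = build_static_tree(4)
        g = Graph(4, [(0, 1), (1, 2), (2, 3)])
        root_es = basic_tree_embeddings(g, tree)
        path4 = _node(tree, [(0, 1), (1, 2), (2, 3)], 4)
        es = tree_census_step(tree, g, tree.root, root_es, path4)
        assert len(es.embeddings) == 1
        assert set(es.embeddings[0]) == {0, 1, 2, 3}

    def test_star_target(self):
        tree = build_static_tree(4)
        g = Graph(4, [(0, 1), (0, 2), (0, 3)])
        root_es = basic_tree_embeddings(g, tree)
        path4 = _node(tree, [(0, 1), (1, 2), (2, 3)], 4)
        star4 = _node(tree, [(0, 1), (0, 2), (0, 3)], 4)
        assert len(tree_census_step(tree, g, tree.root, root_es, path4).embeddings) == 0
        assert len(tree_census_step(tree, g, tree.root, root_es, star4).embeddings) == 1

    def test_no_repeated_vertices(self):
        tree = build_static_tree(4)
        rng = random.Random(4)
        g = random_connected_graph(8, rng, p=0.5)
        root_es = basic_tree_embeddings(g, tree)
        for child in tree.root.children:
            es = tree_census_step(tree, g, tree.root, root_es, child)
            assert all(len(set(e)) == 4 for e in es.embeddings)

    def test_unlinked_child_rejected(self):
        tree = build_static_tree(4)
        g = Graph(4, [(0, 1), (1, 2), (2, 3)])
        root_es = basic_tree_embeddings(g, tree)
        path4 = _node(tree, [(0, 1), (1, 2), (2, 3)], 4)
        star4 = _node(tree, [(0, 1), (0, 2), (0, 3)], 4)
        with pytest.raises(ValueError):
            tree_census_step(tree, g, path4, root_es, star4)


class TestGraphCensusStep:
    def test_cycle_closure(self):
        tree = build_static_tree(4)
        g = Graph(4, [(0, 1), (1, 2), (2, 3), (0, 3)])  # 4-cycle
        root_es = basic_tree_embeddings(g, tree)
        path4 = _node(tree, [(0, 1), (1, 2), (2, 3)], 4)
        c4 = _node(tree, [(0, 1), (1, 2), (2, 3), (0, 3)], 4)
        p4_es = tree_census_step(tree, g, tree.root, root_es, path4)
        es = graph_census_step(tree, g, path4, p4_es, c4)
        assert len(es.embeddings) >= 1
        for emb in es.embeddings:
            assert image_edges(c4, emb) == frozenset(g.edges)

    def test_missing_closing_edge(self):
        tree = build_static_tree(4)
        g = Graph(4, [(0, 1), (1, 2), (2, 3)])  # open path
        root_es = basic_tree_embeddings(g, tree)
        path4 = _node(tree, [(0, 1), (1, 2), (2, 3)], 4)
        c4 = _node(tree, [(0, 1), (1, 2), (2, 3), (0, 3)], 4)
        p4_es = tree_census_step(tree, g, tree.root, root_es, path4)
        assert graph_census_step(tree, g, path4, p4_es, c4).embeddings == []

    def test_k4_single_occurrence_after_dedup(self, k4):
        recs = run_census(make_root(4), k4, 4, 1, propagate="full")
        by_edges = {r.node.n_edges: r for r in recs}
        assert len(by_edges[6].embeddings.embeddings) == 1


class TestRunCensus:
    def test_triangle_reports_both_size3_patterns(self, triangle):
        recs = run_census(make_root(3), triangle, 3, 1)
        got = {r.node.n_edges: r.f2 for r in recs}
        assert got == {2: 1, 3: 1}

    def test_path10_triangle_branch_dies(self):
        g = Graph(10, [(i, i + 1) for i in range(9)])
        recs = run_census(make_root(3), g, 3, 1)
        got = {r.node.n_edges: r.f2 for r in recs}
        assert got[2] >= 1 and got[3] == 0

    def test_two_disjoint_k4(self):
        edges = []
        for off in (0, 4):
            edges += [(off + i, off + j) for i in range(4) for j in range(i + 1, 4)]
        g = Graph(8, edges)
        recs = run_census(make_root(4), g, 4, 2)
        k4_rec = next(r for r in recs if r.node.n_edges == 6)
        assert k4_rec.f2 == 2

    def test_mismatched_tree_size_rejected(self, triangle):
        with pytest.raises(ValueError):
            run_census(make_root(4), triangle, 3, 1)

    def test_oracle_equivalence_small(self):
        """Pre-MIS embedding lists match brute-force subgraph matching on a
        few random graphs, every pattern of size 3 and 4."""
        from mdet import all_small_graphs

        patterns = {
            k: {canonical_form(p).canon_string: p for p in all_small_graphs(k)}
            for k in (3, 4)
        }
        rng = random.Random(23)
        for trial in range(6):
            g = random_connected_graph(rng.randint(6, 10), rng, p=0.35)
            for k in (3, 4):
                recs = run_census(make_root(k), g, k, 1, propagate="full")
                got = {
                    r.node.canon_string: {
                        image_edges(r.node, e) for e in r.embeddings.embeddings
                    }
                    for r in recs
                }
                for cs, pat in patterns[k].items():
                    assert got.get(cs, set()) == oracle_occurrences(g, pat)

    def test_embedding_inheritance(self):
        """Every child embedding's vertex set contains (vertex addition) or
        equals (edge addition) a parent embedding's vertex set."""
        rng = random.Random(31)
        g = random_connected_graph(10, rng, p=0.35)
        recs = run_census(make_root(4), g, 4, 1, propagate="full", keep_interior=True)
        by_node = {id(r.node): r for r in recs}
        for rec in recs:
            if not rec.node.parent_links:
                continue
            parent = rec.node.parent_links[0].parent
            parent_rec = by_node.get(id(parent))
            if parent_rec is None:
                continue
            parent_sets = [frozenset(e) for e in parent_rec.embeddings.embeddings]
            for emb in rec.embeddings.embeddings:
                s = frozenset(emb)
                if rec.node.level_kind == "vertex":
                    assert any(ps < s for ps in parent_sets)
                else:
                    assert s in parent_sets

    def test_no_canonicalization_during_expansion(self):
        """On a pre-built tree the census performs zero canonical-form
        computations: embeddings flow through stored maps only."""
        tree = build_static_tree(4)
        rng = random.Random(8)
        g = random_connected_graph(9, rng, p=0.4)
        before = canonical_mod.CANONICAL_CALLS
        run_census(tree, g, 4, 1, propagate="full")
        assert canonical_mod.CANONICAL_CALLS == before
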