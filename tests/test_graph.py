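"""Core data model: inversion, enrichment, components, conflicts, penalty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhiden import (
    EvolvingSequence,
    Hierarchy,
    Network,
    NodeSets,
    complementary_set,
    conflicting_edges,
    dynamic_set,
    edge_diff,
    induced_subgraph,
    penalty,
)
from dhiden.graph import IncompleteHierarchyError

from .conftest import random_hierarchy, random_network


def net(*edges, nodes=()):
    return Network.from_edges(edges, nodes)


class TestNetworkBasics:
    def test_self_loops_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="self-loop"):
            n = net(("a", "b"), ("a", "a"))
        assert n.edges == {("a", "b")}
        assert "a" in n.nodes  # the node survives, only the loop is dropped

    def test_duplicate_edges_collapse(self):
        n = net(("a", "b"), ("a", "b"))
        assert n.n_edges == 1

    def test_edge_endpoint_must_be_node(self):
        with pytest.raises(ValueError, match="outside node set"):
            Network(frozenset("ab"), frozenset({("a", "c")}))

    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([("a", "b")], {("b", "a")}),
            ([("a", "b"), ("b", "a")], {("a", "b"), ("b", "a")}),
        ],
    )
    def test_invert(self, edges, expected):
        assert net(*edges).invert().edges == expected

    def test_invert_is_involution(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = random_network(rng, 8, 14)
            assert n.invert().invert() == n

    def test_direction_enrich(self):
        n = net(("a", "b"), ("b", "c"))
        assert n.direction_enrich().edges == {
            ("a", "b"),
            ("b", "a"),
            ("b", "c"),
            ("c", "b"),
        }

    def test_direction_enrich_idempotent_on_symmetric_input(self):
        n = net(("a", "b"), ("b", "a"))
        assert n.direction_enrich() == n

    def test_components_partition(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = random_network(rng, 12, 10)
            comps = n.components()
            all_nodes = [v for c in comps for v in c.nodes]
            assert len(all_nodes) == len(set(all_nodes)) == n.n_nodes
            all_edges = {e for c in comps for e in c.edges}
            assert all_edges == n.edges  # no edge crosses components

    def test_components_examples(self):
        two = net(("a", "b"), nodes=["c"]).components()
        assert sorted(len(c.nodes) for c in two) == [1, 2]
        assert len(net(("a", "b"), ("c", "d")).components()) == 2
        assert len(net(("a", "b"), ("b", "c")).components()) == 1


class TestHierarchy:
    def test_level_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            Hierarchy({"a": 4}, 3)
        with pytest.raises(ValueError):
            Hierarchy({"a": 0}, 3)

    def test_missing_level_raises(self):
        h = Hierarchy({"a": 1}, 3)
        with pytest.raises(IncompleteHierarchyError):
            h["b"]


class TestConflictsAndPenalty:
    def test_equal_levels_conflict(self):
        # the defining example: source at or below its target conflicts
        n = net(("4", "5"), ("5", "3"))
        h = Hierarchy({"4": 1, "5": 1, "3": 2}, 3)
        assert conflicting_edges(n, h) == {("4", "5"), ("5", "3")}
        assert penalty(n, h) == 2

    def test_downward_edge_not_conflicting(self):
        n = net(("u", "v"))
        assert penalty(n, Hierarchy({"u": 3, "v": 1}, 3)) == 0

    def test_chain_zero_penalty(self):
        n = net(("a", "b"), ("b", "c"))
        assert penalty(n, Hierarchy({"a": 3, "b": 2, "c": 1}, 3)) == 0

    def test_single_level_hierarchy_conflicts_everywhere(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = random_network(rng, 9, 15)
            h = Hierarchy({v: 1 for v in n.nodes}, 1)
            assert penalty(n, h) == n.n_edges

    def test_penalty_equals_conflict_count(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = random_network(rng, 10, 18)
            h = random_hierarchy(rng, n, 4)
            assert penalty(n, h) == len(conflicting_edges(n, h))

    def test_mirror_symmetry_of_strict_conflicts(self):
        # reversing all edges and flipping levels l -> M+1-l maps strictly
        # conflicting edges onto strictly conflicting edges; equal-level
        # edges stay equal-level, so the penalty is invariant
        rng = np.random.default_rng(4)
        M = 4
        for _ in range(30):
            n = random_network(rng, 8, 14)
            h = random_hierarchy(rng, n, M)
            mirrored = Hierarchy({v: M + 1 - h[v] for v in n.nodes}, M)
            assert penalty(n, h) == penalty(n.invert(), mirrored)


class TestDiffsAndSets:
    def test_edge_diff_example(self):
        prev = net(("2", "4"), ("4", "5"))
        nxt = net(("4", "5"), ("4", "3"))
        ins, dele = edge_diff(prev, nxt)
        assert ins == {("4", "3")} and dele == {("2", "4")}

    def test_edge_diff_identity_and_disjoint(self):
        a = net(("a", "b"), ("b", "c"))
        assert edge_diff(a, a) == (set(), set())
        b = net(("x", "y"))
        ins, dele = edge_diff(a, b)
        assert len(ins) == 1 and len(dele) == 2

    def test_dynamic_set(self):
        h1 = Hierarchy({"a": 1, "b": 2, "c": 3}, 5)
        assert dynamic_set(h1, h1) == set()
        h2 = Hierarchy({"a": 1, "b": 4, "c": 3}, 5)
        assert dynamic_set(h1, h2) == {"b"}
        h3 = Hierarchy({"a": 2, "b": 3, "c": 4}, 5)
        assert dynamic_set(h1, h3) == {"a", "b", "c"}

    def test_complementary_set(self):
        star = net(("hub", "l1"), ("hub", "l2"), ("l3", "hub"))
        assert complementary_set(star, set()) == set()
        assert complementary_set(star, {"hub"}) == {"l1", "l2", "l3"}
        assert complementary_set(star, set(star.nodes)) == set()

    def test_induced_subgraph(self):
        path = net(("a", "b"), ("b", "c"))
        sets = NodeSets.from_dynamic(path, {"b"})
        assert sets.complementary == {"a", "c"}
        sub = induced_subgraph(path, sets)
        assert sub.edges == path.edges
        lone = NodeSets(frozenset({"a"}), frozenset())
        assert induced_subgraph(net(("a", "b"), nodes=()), lone).n_edges == 0
        full = NodeSets.from_dynamic(path, set(path.nodes))
        assert induced_subgraph(path, full) == path

    def test_nodesets_disjointness(self):
        with pytest.raises(ValueError, match="disjoint"):
            NodeSets(frozenset("a"), frozenset("a"))


NODES = [f"g{i}" for i in range(8)]

digraphs = st.builds(
    lambda pairs: Network.from_edges(
        [(NODES[a], NODES[b]) for a, b in pairs if a != b], nodes=NODES[:2]
    ),
    st.lists(
        st.tuples(st.integers(0, 7), st.integers(0, 7)), max_size=20
    ),
)

hierarchies = st.builds(
    lambda levels: Hierarchy(dict(zip(NODES, levels)), 4),
    st.lists(st.integers(1, 4), min_size=8, max_size=8),
)


class TestStructuralProperties:
    @settings(derandomize=True, max_examples=60)
    @given(digraphs)
    def test_inversion_is_involution_and_preserves_size(self, g):
        gi = g.invert()
        assert gi.n_edges == g.n_edges
        assert gi.invert() == g

    @settings(derandomize=True, max_examples=60)
    @given(digraphs)
    def test_enrichment_is_symmetric_and_idempotent(self, g):
        ge = g.direction_enrich()
        assert all((v, u) in ge.edges for u, v in ge.edges)
        assert ge.direction_enrich() == ge

    @settings(derandomize=True, max_examples=60)
    @given(digraphs, hierarchies)
    def test_penalty_identity_and_bounds(self, g, h):
        h = h.restrict(g.nodes) if set(h.level) != g.nodes else h
        h = Hierarchy({v: h.level.get(v, 1) for v in g.nodes}, 4)
        p = penalty(g, h)
        assert p == len(conflicting_edges(g, h))
        assert 0 <= p <= g.n_edges

    @settings(derandomize=True, max_examples=60)
    @given(digraphs)
    def test_components_cover_exactly(self, g):
        comps = g.components()
        nodes = [v for c in comps for v in c.nodes]
        assert sorted(nodes) == sorted(g.nodes)
        assert {e for c in comps for e in c.edges} == g.edges


class TestEvolvingSequence:
    def test_tau_enforced(self):
        a = net(("a", "b"))
        b = net(("a", "b"), ("b", "c"), ("c", "d"))
        with pytest.raises(ValueError, match="churn"):
            EvolvingSequence([a, b], tau=1)
        assert len(EvolvingSequence([a, b], tau=2)) == 2

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            EvolvingSequence([])
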