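"""Movement model: classification, training, propagation, ranking."""

import numpy as np
import pytest

from dhiden import (
    Hierarchy,
    Network,
    NodeSets,
    penalty,
    solve_full,
    solve_restricted,
)
from dhiden.movement import (
    MOVEMENT_CLASSES,
    ROLE_CLASSES,
    MovementModels,
    MovementScores,
    build_system,
    classify_movement,
    classify_relationship,
    predict_prior,
    rank_nodes,
    score_movements,
    select_dynamic,
    solve_scores,
    train_conditional,
    train_prior,
)

from .conftest import random_network


def net(*edges, nodes=()):
    return Network.from_edges(edges, nodes)


TOL = 1e-9


class TestClassification:
    @pytest.mark.parametrize(
        "prev,next_,expected",
        [(3, 1, "down"), (2, 2, "same"), (1, 5, "up")],
    )
    def test_movement_class(self, prev, next_, expected):
        assert classify_movement(prev, next_) == expected

    def test_relationship_classes(self):
        g = net(("u", "v"))
        h = Hierarchy({"u": 3, "v": 1}, 5)
        assert classify_relationship("u", "v", g, h) == {1}

        g2 = net(("v", "u"))
        h2 = Hierarchy({"u": 2, "v": 2}, 5)
        assert classify_relationship("u", "v", g2, h2) == {5}

        both = net(("u", "v"), ("v", "u"))
        h3 = Hierarchy({"u": 1, "v": 4}, 5)
        assert classify_relationship("u", "v", both, h3) == {3, 6}

    def test_relationship_requires_an_edge(self):
        g = net(("u", "v"), nodes=["w"])
        with pytest.raises(ValueError, match="not joined"):
            classify_relationship("u", "w", g, Hierarchy(
                {"u": 1, "v": 1, "w": 1}, 3))


def _static_pair():
    """A training pair where the topology changes but no node moves."""
    prev = net(("a", "b"), ("b", "c"), ("a", "c"))
    nxt = net(("a", "b"), ("b", "c"), ("a", "d"), nodes=["c"])
    h = Hierarchy({"a": 3, "b": 2, "c": 1, "d": 1}, 3)
    return prev, nxt, h, h


class TestPriorModel:
    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_prior([])

    def test_triples_are_distributions(self):
        model = train_prior([_static_pair()])
        for role in ROLE_CLASSES:
            assert abs(sum(model[role]) - 1) < TOL

    def test_no_movement_corpus_concentrates_on_stay(self):
        model = train_prior([_static_pair()] * 5)
        # roles actually observed lean heavily toward "same"; smoothing
        # keeps the others uniform
        for role in model.triples:
            down, same, up = model[role]
            assert same >= down and same >= up

    def test_observed_movement_is_counted(self):
        prev = net(("a", "b"))
        nxt = net(("a", "b"), ("b", "c"))  # insert (b, c)
        h1 = Hierarchy({"a": 3, "b": 1, "c": 2}, 3)
        h2 = Hierarchy({"a": 3, "b": 2, "c": 1}, 3)  # source b moved up
        model = train_prior([(prev, nxt, h1, h2)] * 4)
        role = "src_inserted_below"  # b below c before the change
        down, same, up = model[role]
        assert up > same and up > down


class TestPriorPrediction:
    def test_no_change_gives_stay_everywhere(self, small_models):
        g = net(("a", "b"), ("b", "c"))
        h = Hierarchy({"a": 3, "b": 2, "c": 1}, 3)
        table = predict_prior(g, g, h, small_models.prior)
        assert all(t == (0.0, 1.0, 0.0) for t in table.values())

    def test_locality_beyond_one_hop(self, small_models):
        # chain a-b-c-d-e; change touches edge (a,b): d and e are farther
        # than one hop from either endpoint and must keep the stay prior
        prev = net(("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"))
        nxt = net(("b", "a"), ("b", "c"), ("c", "d"), ("d", "e"))
        h = Hierarchy({v: 3 for v in prev.nodes}, 5)
        table = predict_prior(prev, nxt, h, small_models.prior)
        assert table["d"] == (0.0, 1.0, 0.0)
        assert table["e"] == (0.0, 1.0, 0.0)
        assert table["a"] != (0.0, 1.0, 0.0)

    def test_rows_are_distributions(self, small_models):
        rng = np.random.default_rng(8)
        for _ in range(10):
            prev = random_network(rng, 10, 18)
            nxt = random_network(rng, 10, 18)
            nxt = Network(prev.nodes | nxt.nodes, nxt.edges)
            h = Hierarchy(
                {v: int(rng.integers(1, 6)) for v in prev.nodes | nxt.nodes}, 5
            )
            table = predict_prior(prev, nxt, h, small_models.prior)
            for t in table.values():
                assert abs(sum(t) - 1) < TOL


class TestConditionalModel:
    def test_triples_are_distributions(self, small_models):
        for key, t in small_models.conditional.triples.items():
            assert abs(sum(t) - 1) < TOL

    def test_single_edge_training_runs(self):
        g = net(("a", "b"))
        h = Hierarchy({"a": 2, "b": 1}, 3)
        rng = np.random.default_rng(0)
        model = train_conditional(g, h, 5, 3, rng)
        assert len(model.triples) == 18  # 6 psi x 3 conditioning classes

    def test_forced_perturbation_resolves_deterministically(self):
        # chain with the unique conflict-free optimum (3,2,1): freezing the
        # top node at level 1 forces exactly one new conflict, and the
        # anchored re-solve keeps everyone else in place
        g = net(("a", "b"), ("b", "c"))
        h = Hierarchy({"a": 3, "b": 2, "c": 1}, 3)
        res = solve_restricted(
            g, 3,
            NodeSets.from_dynamic(g, {"b", "c"}),
            h.updated({"a": 1}),
            anchor=True,
        )
        assert res.hierarchy["b"] == 2 and res.hierarchy["c"] == 1
        assert res.total_penalty == 1


class TestPropagation:
    def test_isolated_node_rows_are_zero(self, small_models):
        g = net(("a", "b"), nodes=["iso"])
        h = Hierarchy({"a": 2, "b": 1, "iso": 3}, 3)
        f0 = {v: (0.2, 0.5, 0.3) for v in g.nodes}
        A, b, order = build_system(g, h, f0, small_models.conditional, 0.5)
        i = order.index("iso")
        assert np.all(A[3 * i : 3 * i + 3, :] == 0)
        # isolated node's score is its prior alone
        scores = solve_scores(A, b, 0.5, order)
        assert np.allclose(scores.x_star["iso"], (0.2, 0.5, 0.3), atol=1e-9)

    def test_two_node_block_structure(self, small_models):
        g = net(("a", "b"))
        h = Hierarchy({"a": 2, "b": 1}, 3)
        f0 = {v: (0.0, 1.0, 0.0) for v in g.nodes}
        A, b, order = build_system(g, h, f0, small_models.conditional, 0.5)
        assert A.shape == (6, 6)
        # diagonal blocks are zero (no self-coupling); off-diagonal blocks
        # carry the psi-conditionals
        assert np.all(A[:3, :3] == 0) and np.all(A[3:, 3:] == 0)
        assert np.all((A >= 0) & (A <= 1))

    def test_alpha_one_returns_prior(self, small_models):
        g = net(("a", "b"), ("b", "c"))
        h = Hierarchy({"a": 3, "b": 2, "c": 1}, 3)
        f0 = {"a": (0.1, 0.6, 0.3), "b": (0.0, 1.0, 0.0), "c": (0.3, 0.3, 0.4)}
        A, b, order = build_system(g, h, f0, small_models.conditional, 1.0)
        scores = solve_scores(A, b, 1.0, order)
        for v in g.nodes:
            assert np.allclose(scores.x_star[v], f0[v], atol=1e-9)

    def test_fixed_point_residual(self, small_models, small_net):
        h = solve_full(small_net, 5).hierarchy
        f0 = {v: (0.2, 0.6, 0.2) for v in small_net.nodes}
        A, b, order = build_system(
            small_net, h, f0, small_models.conditional, 0.5
        )
        x = np.linalg.solve(np.eye(len(order) * 3) - 0.5 * A, 0.5 * b)
        resid = np.max(np.abs(x - (0.5 * A @ x + 0.5 * b)))
        assert resid < 1e-8

    def test_score_rows_renormalized(self, small_models, small_net):
        h = solve_full(small_net, 5).hierarchy
        mutated = Network(
            small_net.nodes, frozenset(list(small_net.edges)[:-2])
        )
        scores = score_movements(small_net, mutated, h, small_models)
        for v, t in scores.x_star.items():
            assert abs(sum(t) - 1) < TOL
            assert all(0 <= x <= 1 for x in t)


class TestRankingAndSelection:
    def _scores(self, rows, degree=None):
        return MovementScores(rows, 0.5, degree or {})

    def test_lowest_stay_probability_first(self):
        s = self._scores(
            {
                "a": (0.05, 0.9, 0.05),
                "b": (0.25, 0.5, 0.25),
                "c": (0.45, 0.1, 0.45),
            }
        )
        assert rank_nodes(s) == ["c", "b", "a"]

    def test_tie_breaks_are_deterministic(self):
        rows = {v: (0.25, 0.5, 0.25) for v in "abcd"}
        s = self._scores(rows, degree={"a": 1, "b": 5, "c": 5, "d": 2})
        assert rank_nodes(s) == ["b", "c", "d", "a"]

    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(9)
        rows = {}
        for i in range(20):
            t = rng.dirichlet([1, 1, 1])
            rows[f"v{i}"] = tuple(t)
        ranked = rank_nodes(self._scores(rows))
        assert sorted(ranked) == sorted(rows)

    def test_select_dynamic_sizes(self):
        ranked = [f"v{i}" for i in range(50)]
        assert len(select_dynamic(ranked, 10)) == 10
        assert len(select_dynamic(ranked, 0.2)) == 10
        assert select_dynamic(ranked, 0, new_nodes={"fresh"}) == {"fresh"}
        top = select_dynamic(ranked, 3)
        assert top == {"v0", "v1", "v2"}


class TestEnrichment:
    def test_movers_rank_above_uniform(self, small_models):
        """Nodes that truly change level between consecutive optima must
        sit significantly higher in the predicted ranking than a uniform
        random ordering (one-sided permutation test, p < 0.05).

        Truth is computed afterwards from exhaustive solves of both
        networks (successor solve anchored on the predecessor so that
        'moved' is well defined under optimum degeneracy).
        """
        from dhiden import (
            GeneratorConfig,
            MutationConfig,
            dynamic_set,
            generate_sequence,
            solve_full,
        )

        norm_ranks: list[float] = []
        for rep in range(30):
            seq = generate_sequence(
                GeneratorConfig(50, 2, seed=1000 + rep),
                2,
                MutationConfig(0.1, seed=2000 + rep),
            )
            g1, g2 = seq[0], seq[1]
            h1 = solve_full(g1, 5).hierarchy
            h2 = solve_full(g2, 5, anchor=h1).hierarchy
            moved = dynamic_set(h1, h2)
            if not moved:
                continue
            ranked = rank_nodes(score_movements(g1, g2, h1, small_models))
            pos = {v: i for i, v in enumerate(ranked)}
            n = len(ranked)
            norm_ranks += [pos[v] / (n - 1) for v in moved]
        obs = float(np.mean(norm_ranks))
        rng = np.random.default_rng(4242)
        perm = rng.random((5000, len(norm_ranks))).mean(axis=1)
        p_value = float(np.mean(perm <= obs))
        assert obs < 0.5
        assert p_value < 0.05


class TestSerializationAndDeterminism:
    def test_json_round_trip(self, small_models):
        doc = small_models.to_json()
        back = MovementModels.from_json(doc)
        assert back.prior.triples == small_models.prior.triples
        assert back.conditional.triples == small_models.conditional.triples
        assert back.alpha == small_models.alpha

    def test_training_is_deterministic(self):
        from dhiden.pipeline import PipelineConfig, fit_movement_models

        make = lambda: fit_movement_models(
            PipelineConfig(max_level=4, seed=77),
            n_pairs=4,
            n_perturbations=10,
            train_nodes=20,
        )
        a, b = make(), make()
        assert a.prior.triples == b.prior.triples
        assert a.conditional.triples == b.conditional.triples
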