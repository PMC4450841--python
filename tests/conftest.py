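"""Shared fixtures: toy networks and (cheap) trained movement models."""

from __future__ import annotations

import numpy as np
import pytest

from dhiden import GeneratorConfig, Hierarchy, Network, generate_scale_free
from dhiden.ilp import SolverOptions
from dhiden.pipeline import PipelineConfig, fit_movement_models


@pytest.fixture(scope="session")
def toy_network() -> Network:
    """A seven-node regulatory toy network.

    Contains the regulatory chain 2 -> 4 -> 5 -> 3 and a feedback path
    through 7; its optimal three-level decomposition has penalty exactly 2
    (verified against exhaustive enumeration in the ILP tests).
    """
    return Network.from_edges(
        [
            ("2", "1"),
            ("2", "4"),
            ("2", "5"),
            ("3", "7"),
            ("4", "5"),
            ("5", "3"),
            ("7", "2"),
            ("7", "6"),
        ]
    )


@pytest.fixture(scope="session")
def toy_network_mutated(toy_network) -> Network:
    """The toy network after one rewiring event: edge (2,4) removed and
    edge (4,3) inserted."""
    edges = set(toy_network.edges) - {("2", "4")} | {("4", "3")}
    return Network(toy_network.nodes, frozenset(edges))


def random_network(rng: np.random.Generator, n: int, m: int) -> Network:
    """Uniform random simple digraph with n nodes, ~m edges (test helper)."""
    nodes = [f"n{i}" for i in range(n)]
    edges = set()
    for _ in range(4 * m):
        u, v = rng.integers(n), rng.integers(n)
        if u != v:
            edges.add((nodes[u], nodes[v]))
        if len(edges) >= m:
            break
    return Network.from_edges(edges, nodes)


def random_hierarchy(
    rng: np.random.Generator, net: Network, M: int
) -> Hierarchy:
    return Hierarchy(
        {v: int(rng.integers(1, M + 1)) for v in net.nodes}, M
    )


@pytest.fixture(scope="session")
def fast_solver() -> SolverOptions:
    return SolverOptions(time_limit=60.0)


@pytest.fixture(scope="session")
def small_models():
    """Movement models trained on a deliberately small corpus — enough for
    functional tests, not for accuracy claims (those train their own)."""
    cfg = PipelineConfig(max_level=5, seed=1234)
    return fit_movement_models(
        cfg, n_pairs=10, n_perturbations=40, train_nodes=25
    )


@pytest.fixture(scope="session")
def small_net() -> Network:
    return generate_scale_free(GeneratorConfig(n_nodes=25, density=2, seed=5))
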