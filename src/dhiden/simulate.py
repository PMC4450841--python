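"""Synthetic evolving regulatory networks.

Networks are grown by preferential attachment (Barabási–Albert style), which
reproduces the heavy-tailed degree distribution of real regulatory networks,
and then evolved by degree-preserving edge shuffling: a mutation step picks
two node-disjoint edges ``(u1, v1)`` and ``(u2, v2)`` and replaces them with
``(u1, v2)`` and ``(u2, v1)``, preserving every node's in- and out-degree.
Given a mutation rate ``r``, one evolution step applies ``ceil(r * |E| / 2)``
such swaps, so at most a fraction ``r`` of the edges is rewired per step.

The attachment model itself is undirected; edge orientation here is a
declared convention: each new attachment edge initially points from the new
node to the chosen existing node, and is then flipped with probability 0.5.
A pure new->old orientation would make every generated network acyclic,
which would make hierarchy decomposition trivially conflict-free at
sufficient depth — unrealistically easy for the methods under study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import Edge, EvolvingSequence, Network

__all__ = [
    "GeneratorConfig",
    "MutationConfig",
    "generate_scale_free",
    "degree_preserving_swap",
    "mutate",
    "generate_sequence",
    "node_churn",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Scale-free generator parameters.

    ``density`` is the target number of edges per node; non-integer densities
    alternate each new node's attachment count between floor and ceil.
    """

    n_nodes: int
    density: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if math.floor(self.density) < 1 or self.n_nodes <= self.density:
            raise ValueError(
                f"infeasible generator parameters: n_nodes={self.n_nodes}, "
                f"density={self.density}"
            )


@dataclass(frozen=True)
class MutationConfig:
    """Degree-preserving shuffle parameters; ``rate`` is the fraction of
    edges involved in swaps per evolution step (default matches the study
    conditions)."""

    rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def _node_name(i: int, width: int) -> str:
    return f"g{i:0{width}d}"


def _attachment_counts(cfg: GeneratorConfig, n_new: int) -> list[int]:
    lo, hi = math.floor(cfg.density), math.ceil(cfg.density)
    if lo == hi:
        return [lo] * n_new
    frac = cfg.density - lo
    counts = []
    acc = 0.0
    for _ in range(n_new):
        acc += frac
        if acc >= 1.0 - 1e-12:
            counts.append(hi)
            acc -= 1.0
        else:
            counts.append(lo)
    return counts


def generate_scale_free(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> Network:
    """Grow a weakly connected directed scale-free network.

    Seed graph: a short chain over ``ceil(density) + 1`` nodes.  Each
    subsequent node attaches to ``~density`` distinct existing nodes chosen
    with probability proportional to total degree, after which each new
    edge's direction is flipped with probability 0.5.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    width = len(str(n - 1)) + 1
    m0 = min(max(2, math.ceil(cfg.density) + 1), n)
    names = [_node_name(i, width) for i in range(n)]

    edges: set[Edge] = set()
    # endpoint multiset for preferential sampling (one entry per edge end)
    endpoints: list[int] = []

    def add_edge(a: int, b: int) -> None:
        e = (names[a], names[b]) if rng.random() < 0.5 else (names[b], names[a])
        edges.add(e)
        endpoints.append(a)
        endpoints.append(b)

    for i in range(1, m0):
        add_edge(i - 1, i)

    counts = _attachment_counts(cfg, n - m0)
    for k, i in enumerate(range(m0, n)):
        m = min(counts[k], i)
        targets: set[int] = set()
        while len(targets) < m:
            # mix of preferential and uniform choice keeps early nodes from
            # absorbing everything while preserving the heavy tail
            if endpoints and rng.random() < 0.9:
                t = int(endpoints[rng.integers(len(endpoints))])
            else:
                t = int(rng.integers(i))
            targets.add(t)
        for t in sorted(targets):
            add_edge(i, t)

    return Network(frozenset(names), frozenset(edges))


def degree_preserving_swap(
    net: Network, rng: np.random.Generator, max_attempts: int | None = None
) -> tuple[Network, bool]:
    """Apply one endpoint swap to two uniformly chosen node-disjoint edges.

    Swaps that would create a self-loop or a duplicate edge are rejected and
    re-drawn.  Returns ``(network, applied)``; ``applied`` is False when no
    valid swap was found within the attempt budget (degenerate inputs).
    """
    edges = sorted(net.edges)
    m = len(edges)
    if m < 2:
        return net, False
    if max_attempts is None:
        max_attempts = 100 * m
    edge_set = set(edges)
    for _ in range(max_attempts):
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        (u1, v1), (u2, v2) = edges[i], edges[j]
        if len({u1, v1, u2, v2}) < 4:
            continue  # edges share a node
        e1, e2 = (u1, v2), (u2, v1)
        if e1 in edge_set or e2 in edge_set:
            continue
        new_edges = edge_set - {(u1, v1), (u2, v2)} | {e1, e2}
        return Network(net.nodes, frozenset(new_edges)), True
    return net, False


def n_swaps(rate: float, n_edges: int) -> int:
    """Number of swap steps for one evolution step: ``ceil(rate * |E| / 2)``."""
    return math.ceil(rate * n_edges / 2)


def mutate(
    net: Network,
    cfg: MutationConfig,
    rng: np.random.Generator | None = None,
) -> Network:
    """One evolution step: ``ceil(rate * |E| / 2)`` accepted degree-preserving
    swaps."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = net
    for _ in range(n_swaps(cfg.rate, net.n_edges)):
        out, applied = degree_preserving_swap(out, rng)
        if not applied:
            break
    return out


def generate_sequence(
    gen: GeneratorConfig, K: int, mut: MutationConfig
) -> EvolvingSequence:
    """An evolving sequence G_1..G_K: G_1 from the scale-free generator, each
    later member one mutation step of its predecessor.  Fully reproducible
    from the two seeds."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(gen.seed)
    mut_rng = np.random.default_rng(mut.seed)
    nets = [generate_scale_free(gen, rng)]
    for _ in range(1, K):
        nets.append(mutate(nets[-1], mut, mut_rng))
    swaps = n_swaps(mut.rate, nets[0].n_edges)
    tau = 4 * swaps  # each swap changes at most 4 edges of the symmetric diff
    return EvolvingSequence(
        nets,
        tau=tau if K > 1 else None,
        meta={
            "n_nodes": gen.n_nodes,
            "density": gen.density,
            "generator_seed": gen.seed,
            "mutation_rate": mut.rate,
            "mutation_seed": mut.seed,
            "K": K,
        },
    )


def node_churn(
    net: Network,
    n_insert: int,
    n_delete: int,
    rng: np.random.Generator,
    edges_per_node: int = 2,
) -> Network:
    """Delete ``n_delete`` uniformly chosen nodes (with incident edges) and
    insert ``n_insert`` fresh nodes wired by preferential attachment."""
    if n_delete >= net.n_nodes:
        raise ValueError("cannot delete all nodes")
    nodes = sorted(net.nodes)
    doomed = set(
        np.array(nodes)[rng.choice(len(nodes), size=n_delete, replace=False)]
    ) if n_delete else set()
    keep = [v for v in nodes if v not in doomed]
    edges = {e for e in net.edges if e[0] not in doomed and e[1] not in doomed}

    deg = {v: 0 for v in keep}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    existing = list(keep)
    suffix = 0
    taken = set(net.nodes)
    for _ in range(n_insert):
        while f"new{suffix}" in taken:
            suffix += 1
        name = f"new{suffix}"
        taken.add(name)
        weights = np.array([deg[v] + 1 for v in existing], dtype=float)
        weights /= weights.sum()
        m = min(edges_per_node, len(existing))
        targets = rng.choice(len(existing), size=m, replace=False, p=weights)
        deg[name] = 0
        for t in sorted(int(x) for x in targets):
            tgt = existing[t]
            e = (name, tgt) if rng.random() < 0.5 else (tgt, name)
            edges.add(e)
            deg[name] += 1
            deg[tgt] += 1
        existing.append(name)
    return Network(frozenset(existing), frozenset(edges))
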