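"""Static hierarchy-decomposition baselines.

Five comparison methods, each producing a total hierarchy over 1..M for any
directed network (cyclic or not):

* ``bfs_hierarchy`` — breadth-first levels from the in-degree-zero roots;
  simple, but has no mechanism to resolve cycles.
* ``vertex_sort`` — topological sort of the strongly-connected-component
  condensation; yields a *range* of admissible levels per node, collapsed to
  the range midpoint for penalty comparison.
* ``hino`` — BFS followed by iterated "downgrade" (drop each node to the
  lowest level among itself and its regulators) and "upgrade" (raise nodes
  that regulate a same-level node and have no regulator themselves)
  correction sweeps.
* exhaustive ILP (``dhiden.ilp.solve_full``) — the exact optimum.
* ``dc_hiden`` — divide-and-conquer: exact ILP on random connected
  subnetworks with frozen boundaries, merged until every node is assigned,
  plus optional re-optimization passes.  Scales beyond the exhaustive solve
  at some cost in optimality.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import Hierarchy, Network, NodeSets, penalty
from .ilp import SolverOptions, solve_full, solve_restricted

__all__ = [
    "LevelRange",
    "DcConfig",
    "bfs_hierarchy",
    "vertex_sort",
    "hino",
    "dc_hiden",
]


@dataclass(frozen=True)
class LevelRange:
    """Admissible level interval for one node (vertex-sort output)."""

    node: str
    low: int
    high: int

    def __post_init__(self) -> None:
        if not 1 <= self.low <= self.high:
            raise ValueError(f"invalid range [{self.low}, {self.high}]")

    @property
    def midpoint(self) -> int:
        return -((self.low + self.high) // -2)  # ceil division


@dataclass(frozen=True)
class DcConfig:
    """Divide-and-conquer solver parameters.

    The plain method covers the network once with locally exact solves
    (``passes=0``); optional refinement passes re-optimize random balls and
    can only lower the penalty, but go beyond the original cover-and-merge
    scheme, so they are off by default.
    """

    subnet_size: int = 50
    passes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subnet_size < 2:
            raise ValueError("subnet_size must be >= 2")
        if self.passes < 0:
            raise ValueError("passes must be >= 0")


# ---------------------------------------------------------------------------


def _component_roots(comp: Network) -> list[str]:
    """Zero-in-degree nodes; if none exist (cyclic core), fall back to the
    max-out-degree node (ties to the smallest identifier)."""
    indeg = comp.in_degree()
    roots = sorted(v for v, d in indeg.items() if d == 0)
    if roots:
        return roots
    outdeg = comp.out_degree()
    return [min(comp.nodes, key=lambda v: (-outdeg[v], v))]


def bfs_hierarchy(net: Network, M: int) -> Hierarchy:
    """Breadth-first levels: distance d from the nearest root maps to level
    ``M - min(d, M - 1)``; nodes unreachable from any root along edge
    direction are placed at the bottom level."""
    levels: dict[str, int] = {}
    for comp in net.components():
        out_adj: dict[str, list[str]] = {v: [] for v in comp.nodes}
        for u, v in sorted(comp.edges):
            out_adj[u].append(v)
        dist = {r: 0 for r in _component_roots(comp)}
        queue = deque(sorted(dist))
        while queue:
            u = queue.popleft()
            for v in out_adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for v in comp.nodes:
            d = dist.get(v, M - 1)
            levels[v] = M - min(d, M - 1)
    return Hierarchy(levels, M)


def vertex_sort(net: Network, M: int) -> tuple[list[LevelRange], Hierarchy]:
    """Topological-sort decomposition on the SCC condensation.

    Within the condensation DAG each node gets the interval
    [1 + longest-path-to-a-sink, L - longest-path-from-a-source] (L = number
    of condensation levels), rescaled monotonically into 1..M; all members
    of an SCC share one interval.  The point hierarchy takes each interval's
    midpoint (rounded up).
    """
    g = net.to_networkx()
    cond = nx.condensation(g)
    order = list(nx.topological_sort(cond))
    # longest path from any source (edge count)
    from_src = {c: 0 for c in cond.nodes}
    for c in order:
        for succ in cond.successors(c):
            from_src[succ] = max(from_src[succ], from_src[c] + 1)
    to_sink = {c: 0 for c in cond.nodes}
    for c in reversed(order):
        for succ in cond.successors(c):
            to_sink[c] = max(to_sink[c], to_sink[succ] + 1)
    L = max((from_src[c] + to_sink[c] for c in cond.nodes), default=0) + 1

    def rescale(x: int) -> int:
        if L <= 1:
            return 1
        return 1 + round((x - 1) * (M - 1) / (L - 1))

    ranges: list[LevelRange] = []
    levels: dict[str, int] = {}
    for c in cond.nodes:
        low = rescale(1 + to_sink[c])
        high = rescale(L - from_src[c])
        for v in cond.nodes[c]["members"]:
            r = LevelRange(v, low, high)
            ranges.append(r)
            levels[v] = r.midpoint
    ranges.sort(key=lambda r: r.node)
    return ranges, Hierarchy(levels, M)


def hino(
    net: Network,
    M: int,
    max_sweeps: int | None = None,
    start: Hierarchy | None = None,
) -> Hierarchy:
    """BFS hierarchy refined by downgrade/upgrade correction sweeps, iterated
    to a fixed point (or a sweep cap of 2*M).  ``start`` overrides the BFS
    initialization (useful for exercising the correction rules)."""
    if start is not None:
        levels = {v: start[v] for v in net.nodes}
    else:
        levels = dict(bfs_hierarchy(net, M).level)
    regulators: dict[str, list[str]] = {v: [] for v in net.nodes}
    regulated: dict[str, list[str]] = {v: [] for v in net.nodes}
    for u, v in sorted(net.edges):
        regulators[v].append(u)
        regulated[u].append(v)
    if max_sweeps is None:
        max_sweeps = 2 * M
    for _ in range(max_sweeps):
        changed = False
        # downgrade: drop v to the lowest level among itself + regulators
        for v in sorted(net.nodes):
            if regulators[v]:
                lo = min([levels[v]] + [levels[u] for u in regulators[v]])
                if lo != levels[v]:
                    levels[v] = lo
                    changed = True
        # upgrade: raise v one level if it regulates a same-level node and
        # nothing regulates v
        for v in sorted(net.nodes):
            if regulators[v]:
                continue
            if any(levels[w] == levels[v] for w in regulated[v]):
                new = min(levels[v] + 1, M)
                if new != levels[v]:
                    levels[v] = new
                    changed = True
        if not changed:
            break
    return Hierarchy(levels, M)


# ---------------------------------------------------------------------------


def _bfs_ball(
    start: str, adj: dict[str, list[str]], size: int
) -> set[str]:
    """Deterministic BFS ball of at most ``size`` nodes on the enriched
    (undirected) adjacency."""
    ball = {start}
    queue = deque([start])
    while queue and len(ball) < size:
        u = queue.popleft()
        for v in adj[u]:
            if v not in ball:
                ball.add(v)
                queue.append(v)
                if len(ball) >= size:
                    break
    return ball


def dc_hiden(
    net: Network,
    M: int,
    cfg: DcConfig | None = None,
    opts: SolverOptions | None = None,
) -> Hierarchy:
    """Divide-and-conquer decomposition.

    Cover phase: repeatedly grow a BFS ball of at most ``subnet_size`` nodes
    around a random unassigned node, solve it exactly while freezing
    already-assigned nodes on its boundary, until everyone has a level.
    Refinement phase: ``passes`` rounds of re-optimizing random balls with
    frozen boundaries; each round solves a restricted problem whose feasible
    set contains the incumbent, so the penalty never increases.
    """
    cfg = cfg or DcConfig()
    opts = opts or SolverOptions()
    rng = np.random.default_rng(cfg.seed)
    if net.n_nodes <= cfg.subnet_size:
        return solve_full(net, M, opts).hierarchy

    adj = {v: sorted(nbrs) for v, nbrs in net.neighbor_map().items()}
    levels: dict[str, int] = {}
    unassigned = set(net.nodes)
    while unassigned:
        pool = sorted(unassigned)
        start = pool[rng.integers(len(pool))]
        ball = _bfs_ball(start, adj, cfg.subnet_size)
        free = ball & unassigned
        boundary = {
            u
            for v in free
            for u in adj[v]
            if u in levels
        }
        sub = net.subgraph(free | boundary)
        res = solve_restricted(
            sub,
            M,
            NodeSets.from_dynamic(sub, free),
            Hierarchy({v: levels[v] for v in boundary}, M),
            opts,
        )
        for v in free:
            levels[v] = res.hierarchy[v]
        unassigned -= free

    h = Hierarchy(levels, M)
    for _ in range(cfg.passes):
        pool = sorted(net.nodes)
        start = pool[rng.integers(len(pool))]
        free = _bfs_ball(start, adj, cfg.subnet_size)
        sets = NodeSets.from_dynamic(net, free)
        res = solve_restricted(net, M, sets, h, opts)
        if penalty(net, res.hierarchy) <= penalty(net, h):
            h = res.hierarchy
    return h
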