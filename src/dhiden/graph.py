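"""Directed gene-regulatory-network data model and hierarchy bookkeeping.

A regulatory network is a directed graph ``G = (V, E)`` whose nodes are gene
identifiers and whose edges are regulatory interactions (regulator -> target).
A *hierarchical decomposition* assigns each gene an integer level in
``{1, ..., M}``; larger levels sit higher in the regulatory hierarchy
(master regulators at the top).  An edge ``(u, v)`` is *conflicting* when
``level(u) <= level(v)`` — regulation should flow strictly downward — and the
*penalty* of a decomposition is the number of conflicting edges.  Penalty is
the sole quality objective used throughout this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Network",
    "Hierarchy",
    "EvolvingSequence",
    "NodeSets",
    "conflicting_edges",
    "penalty",
    "edge_diff",
    "dynamic_set",
    "complementary_set",
    "induced_subgraph",
]

Edge = tuple[str, str]


class IncompleteHierarchyError(KeyError):
    """A node of the network has no level in the supplied hierarchy."""


@dataclass(frozen=True)
class Network:
    """An immutable directed network over named genes.

    Edges form a set (no multiplicity); self-loops are rejected at
    construction — a self-loop is conflicting under every possible hierarchy,
    so it carries no decomposition information and would only shift every
    penalty by a constant.
    """

    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop ({u!r},{v!r}) is not allowed")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r},{v!r}) has endpoint outside node set")

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], nodes: Iterable[str] = ()
    ) -> "Network":
        """Build a network from an edge iterable, de-duplicating edges and
        dropping self-loops with a warning.  ``nodes`` may add isolated nodes.
        """
        node_set: set[str] = set(nodes)
        edge_set: set[Edge] = set()
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                node_set.add(u)
                continue
            edge_set.add((u, v))
            node_set.add(u)
            node_set.add(v)
        if n_loops:
            warnings.warn(f"dropped {n_loops} self-loop(s)", stacklevel=2)
        return cls(frozenset(node_set), frozenset(edge_set))

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, v: str) -> frozenset[str]:
        """All nodes joined to ``v`` by an edge in either direction."""
        out = {t for s, t in self.edges if s == v}
        out |= {s for s, t in self.edges if t == v}
        return frozenset(out)

    def neighbor_map(self) -> dict[str, set[str]]:
        """Undirected adjacency for all nodes (empty set for isolated ones)."""
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def in_degree(self) -> dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for _, t in self.edges:
            deg[t] += 1
        return deg

    def out_degree(self) -> dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for s, _ in self.edges:
            deg[s] += 1
        return deg

    def total_degree(self) -> dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for s, t in self.edges:
            deg[s] += 1
            deg[t] += 1
        return deg

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- structural operations --------------------------------------------

    def invert(self) -> "Network":
        """The inverse network: every edge reversed."""
        return Network(self.nodes, frozenset((v, u) for u, v in self.edges))

    def direction_enrich(self) -> "Network":
        """The direction-enriched network: union of the edges and their
        reversals.  Connectivity of a directed network is defined on this
        symmetric graph."""
        enriched = set(self.edges)
        enriched.update((v, u) for u, v in self.edges)
        return Network(self.nodes, frozenset(enriched))

    def components(self) -> list["Network"]:
        """Split into maximal connected components of the direction-enriched
        graph (= weakly connected components).  Sorted by smallest member for
        determinism; their union recovers the network."""
        comps = nx.weakly_connected_components(self.to_networkx())
        nets = []
        for comp in comps:
            comp = frozenset(comp)
            nets.append(
                Network(comp, frozenset(e for e in self.edges if e[0] in comp))
            )
        nets.sort(key=lambda n: min(n.nodes))
        return nets

    def subgraph(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph on ``keep`` (must be a subset of the nodes)."""
        keep = frozenset(keep)
        extra = keep - self.nodes
        if extra:
            raise ValueError(f"nodes not in network: {sorted(extra)[:5]}")
        return Network(
            keep, frozenset(e for e in self.edges if e[0] in keep and e[1] in keep)
        )


@dataclass(frozen=True)
class Hierarchy:
    """A total map node -> level in ``{1, ..., max_level}``.

    Level ``max_level`` is the top of the regulatory hierarchy.
    """

    level: Mapping[str, int]
    max_level: int

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise ValueError("max_level must be >= 1")
        object.__setattr__(self, "level", dict(self.level))
        for v, l in self.level.items():
            if not 1 <= l <= self.max_level:
                raise ValueError(
                    f"level {l} of node {v!r} outside 1..{self.max_level}"
                )

    def __getitem__(self, v: str) -> int:
        try:
            return self.level[v]
        except KeyError:
            raise IncompleteHierarchyError(v) from None

    def __contains__(self, v: str) -> bool:
        return v in self.level

    def __iter__(self) -> Iterator[str]:
        return iter(self.level)

    def __len__(self) -> int:
        return len(self.level)

    def restrict(self, nodes: Iterable[str]) -> "Hierarchy":
        nodes = set(nodes)
        return Hierarchy(
            {v: l for v, l in self.level.items() if v in nodes}, self.max_level
        )

    def updated(self, new_levels: Mapping[str, int]) -> "Hierarchy":
        merged = dict(self.level)
        merged.update(new_levels)
        return Hierarchy(merged, self.max_level)


@dataclass(frozen=True)
class NodeSets:
    """The dynamic node set D (levels free to change) and its complementary
    set C (non-dynamic nodes directly wired to a dynamic node, whose levels
    are frozen in the restricted optimization)."""

    dynamic: frozenset[str]
    complementary: frozenset[str]

    def __post_init__(self) -> None:
        if self.dynamic & self.complementary:
            raise ValueError("dynamic and complementary sets must be disjoint")

    @classmethod
    def from_dynamic(cls, net: Network, dynamic: Iterable[str]) -> "NodeSets":
        dyn = frozenset(dynamic)
        return cls(dyn, frozenset(complementary_set(net, dyn)))

    @property
    def all_nodes(self) -> frozenset[str]:
        return self.dynamic | self.complementary


@dataclass
class EvolvingSequence:
    """An ordered sequence of networks G_1..G_K with bounded edge churn.

    ``tau`` bounds the symmetric edge-set difference between consecutive
    members; ``tau=None`` disables the check (node sets may differ freely —
    node insertion/deletion is handled downstream).
    """

    networks: list[Network]
    tau: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("sequence must contain at least one network")
        if self.tau is not None:
            for i in range(1, len(self.networks)):
                ins, dele = edge_diff(self.networks[i - 1], self.networks[i])
                churn = len(ins) + len(dele)
                if churn > self.tau:
                    raise ValueError(
                        f"edge churn {churn} between steps {i - 1} and {i} "
                        f"exceeds tau={self.tau}"
                    )

    def __len__(self) -> int:
        return len(self.networks)

    def __getitem__(self, i: int) -> Network:
        return self.networks[i]

    def __iter__(self) -> Iterator[Network]:
        return iter(self.networks)


# ---------------------------------------------------------------------------
# free functions on networks + hierarchies


def conflicting_edges(net: Network, h: Hierarchy) -> set[Edge]:
    """Edges ``(u, v)`` with ``level(u) <= level(v)``.

    Equal levels count as conflicting: regulation must flow strictly
    downward to be conflict-free.
    """
    return {(u, v) for u, v in net.edges if h[u] <= h[v]}


def penalty(net: Network, h: Hierarchy) -> int:
    """Number of conflicting edges of ``net`` under ``h``."""
    return sum(1 for u, v in net.edges if h[u] <= h[v])


def edge_diff(prev: Network, next_: Network) -> tuple[set[Edge], set[Edge]]:
    """``(inserted, deleted)`` edge sets between consecutive networks."""
    return (
        set(next_.edges - prev.edges),
        set(prev.edges - next_.edges),
    )


def dynamic_set(h_prev: Hierarchy, h_next: Hierarchy) -> set[str]:
    """Nodes (present in both hierarchies) whose level changed."""
    shared = set(h_prev.level) & set(h_next.level)
    return {v for v in shared if h_prev[v] != h_next[v]}


def complementary_set(net: Network, dynamic: Iterable[str]) -> set[str]:
    """Non-dynamic nodes with at least one edge (either direction) touching a
    dynamic node."""
    dyn = set(dynamic)
    out: set[str] = set()
    for u, v in net.edges:
        if u in dyn and v not in dyn:
            out.add(v)
        elif v in dyn and u not in dyn:
            out.add(u)
    return out


def induced_subgraph(net: Network, sets: NodeSets) -> Network:
    """The subgraph S induced by the dynamic and complementary nodes: the
    restricted optimization sees exactly these nodes and the edges among
    them."""
    return net.subgraph(sets.all_nodes & net.nodes)
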