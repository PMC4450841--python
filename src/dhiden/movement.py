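"""Probabilistic prediction of hierarchy-level movement.

After a topology change, each node either moves down, stays, or moves up in
the optimal hierarchy (the three movement classes down / same / up).  The
incremental decomposer needs to guess *which* nodes will move before solving,
so it can restrict the expensive exact optimization to those nodes.

Prediction combines two learned ingredients:

* a **prior** ``f0(v, .)`` driven by proximity to the topology change: nodes
  far from any inserted or deleted edge get the degenerate prior
  ``(0, 1, 0)`` (certainly staying), while endpoints of changed edges and
  their immediate neighbors get empirical movement frequencies learned from
  a training corpus of perturbed networks (one frequency triple per node
  role: source/target of an inserted/deleted edge, or neighbor of one);

* a **conditional** model ``P_psi(v in phi | u in phi')`` describing how a
  node's movement couples to a neighbor's movement given their relationship
  class psi — the six combinations of connecting-edge direction and relative
  level order (above / equal / below).  It is learned by repeatedly forcing
  a random node to a random different level, re-solving the rest of the
  hierarchy exactly, and recording the co-movements of neighbors.

The two are fused by a damped neighborhood propagation: scores x solve

    x = (1 - alpha) * A x + alpha * b,      x* = (I - (1-alpha) A)^{-1} alpha b

where A carries the neighbor conditionals normalized by degree and b stacks
the priors.  Nodes are then ranked by ascending probability of staying put;
the top of the ranking becomes the predicted dynamic node set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .graph import Edge, Hierarchy, Network, NodeSets, edge_diff
from .ilp import SolverOptions, solve_restricted

__all__ = [
    "MOVEMENT_CLASSES",
    "ROLE_CLASSES",
    "PriorModel",
    "ConditionalModel",
    "MovementModels",
    "MovementScores",
    "classify_movement",
    "classify_relationship",
    "train_prior",
    "predict_prior",
    "train_conditional",
    "build_system",
    "solve_scores",
    "score_movements",
    "rank_nodes",
    "select_dynamic",
]

#: order of the movement classes in every probability triple
MOVEMENT_CLASSES = ("down", "same", "up")
_CLS_INDEX = {c: i for i, c in enumerate(MOVEMENT_CLASSES)}

#: node roles relative to a changed edge, used by the prior model.
#: A changed edge is characterized by its operation (inserted/deleted) and
#: by the relative previous levels of its endpoints: "above" = source above
#: target (the edge is level-consistent), "equal", "below" = source below
#: target (inverted).  An inserted consistent edge forces no movement while
#: an inserted inverted or equal-level edge pressures its endpoints apart —
#: conditioning the roles on this order is what makes the prior
#: discriminative.
#: Neighbors of a changed-edge endpoint are split by their relationship
#: class psi to that endpoint (edge direction x relative level), since how a
#: neighbor is wired to the perturbed node determines whether the
#: perturbation can drag it along.
ROLE_CLASSES = tuple(
    f"{end}_{op}_{rel}"
    for end in ("src", "tgt")
    for op in ("inserted", "deleted")
    for rel in ("above", "equal", "below")
) + tuple(f"neighbor_psi{k}" for k in range(1, 7))

STAY_TRIPLE = (0.0, 1.0, 0.0)


def classify_movement(l_prev: int, l_next: int) -> str:
    """Movement class of a node between two hierarchy levels."""
    if l_next < l_prev:
        return "down"
    if l_next > l_prev:
        return "up"
    return "same"


def classify_relationship(
    u: str, v: str, net: Network, h: Hierarchy
) -> set[int]:
    """Relationship classes psi of the ordered pair (u, v).

    psi 1/2/3: edge (u, v) present and level(u) >/=/< level(v);
    psi 4/5/6: edge (v, u) present and level(u) >/=/< level(v).
    A mutually connected pair gets one class per edge direction.
    """
    out: set[int] = set()
    lu, lv = h[u], h[v]
    rel = 0 if lu > lv else (1 if lu == lv else 2)
    if (u, v) in net.edges:
        out.add(1 + rel)
    if (v, u) in net.edges:
        out.add(4 + rel)
    if not out:
        raise ValueError(f"nodes {u!r} and {v!r} are not joined by an edge")
    return out


def _normalize(counts: np.ndarray) -> tuple[float, float, float]:
    t = counts / counts.sum()
    return (float(t[0]), float(t[1]), float(t[2]))


@dataclass(frozen=True)
class PriorModel:
    """Per-role empirical movement distributions (down, same, up)."""

    triples: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for role, t in self.triples.items():
            if abs(sum(t) - 1.0) > 1e-9:
                raise ValueError(f"triple for role {role!r} does not sum to 1")

    def __getitem__(self, role: str) -> tuple[float, float, float]:
        return self.triples[role]


@dataclass(frozen=True)
class ConditionalModel:
    """``P_psi(v in phi | u in phi')`` triples keyed by (psi, phi')."""

    triples: Mapping[tuple[int, str], tuple[float, float, float]]

    def __post_init__(self) -> None:
        for key, t in self.triples.items():
            if abs(sum(t) - 1.0) > 1e-9:
                raise ValueError(f"triple for {key} does not sum to 1")

    def __getitem__(self, key: tuple[int, str]) -> tuple[float, float, float]:
        return self.triples[key]


@dataclass
class MovementModels:
    """Bundle of the trained prior and conditional models plus provenance."""

    prior: PriorModel
    conditional: ConditionalModel
    alpha: float = 0.5
    n_perturbations: int = 0
    seed: int | None = None

    SCHEMA_VERSION = 1

    def to_json(self) -> str:
        doc = {
            "schema_version": self.SCHEMA_VERSION,
            "alpha": self.alpha,
            "n_perturbations": self.n_perturbations,
            "seed": self.seed,
            "prior": {role: list(t) for role, t in self.prior.triples.items()},
            "conditional": {
                f"{psi}|{phi}": list(t)
                for (psi, phi), t in self.conditional.triples.items()
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MovementModels":
        doc = json.loads(text)
        if doc.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError("unsupported movement-model schema version")
        prior = PriorModel(
            {role: tuple(t) for role, t in doc["prior"].items()}
        )
        cond = {}
        for key, t in doc["conditional"].items():
            psi, phi = key.split("|")
            cond[(int(psi), phi)] = tuple(t)
        return cls(
            PriorModel(prior.triples),
            ConditionalModel(cond),
            alpha=doc["alpha"],
            n_perturbations=doc["n_perturbations"],
            seed=doc["seed"],
        )


# ---------------------------------------------------------------------------
# prior model


def _level_relation(u: str, v: str, h: Hierarchy) -> str:
    if u not in h or v not in h:
        return "equal"  # fresh node: no previous order to condition on
    lu, lv = h[u], h[v]
    return "above" if lu > lv else ("equal" if lu == lv else "below")


def _changed_edge_roles(
    prev: Network, next_: Network, h_prev: Hierarchy
) -> list[tuple[Edge, str, str]]:
    """Yield (edge, role-of-source, role-of-target) for every changed edge,
    with roles conditioned on the endpoints' relative previous levels."""
    inserted, deleted = edge_diff(prev, next_)
    out = []
    for op, edges in (("inserted", inserted), ("deleted", deleted)):
        for u, v in sorted(edges):
            rel = _level_relation(u, v, h_prev)
            out.append(((u, v), f"src_{op}_{rel}", f"tgt_{op}_{rel}"))
    return out


def train_prior(
    pairs: Sequence[tuple[Network, Network, Hierarchy, Hierarchy]],
) -> PriorModel:
    """Learn per-role movement frequencies from observed transitions.

    For every changed edge of every training pair, the movement classes of
    the edge's endpoints (per role) and of their neighbors are counted;
    counts are Laplace-smoothed (add-one) and normalized per role.
    """
    if not pairs:
        raise ValueError("empty training corpus")
    counts = {role: np.zeros(3) for role in ROLE_CLASSES}
    for prev, next_, h_prev, h_next in pairs:
        adj = next_.neighbor_map()

        def movement(v: str) -> str | None:
            if v in h_prev and v in h_next:
                return classify_movement(h_prev[v], h_next[v])
            return None

        for (u, v), role_u, role_v in _changed_edge_roles(prev, next_, h_prev):
            for node, role in ((u, role_u), (v, role_v)):
                m = movement(node)
                if m is not None:
                    counts[role][_CLS_INDEX[m]] += 1
            for endpoint in (u, v):
                for nb in sorted(adj.get(endpoint, ())):
                    if nb in (u, v):
                        continue
                    m = movement(nb)
                    if m is None or nb not in h_prev or endpoint not in h_prev:
                        continue
                    for psi in classify_relationship(nb, endpoint, next_, h_prev):
                        counts[f"neighbor_psi{psi}"][_CLS_INDEX[m]] += 1
    triples = {role: _normalize(c + 1.0) for role, c in counts.items()}
    return PriorModel(triples)


def predict_prior(
    prev: Network,
    next_: Network,
    h_prev: Hierarchy,
    model: PriorModel,
) -> dict[str, tuple[float, float, float]]:
    """Per-node prior f0 over the movement classes for the transition
    ``prev -> next_``.

    Every node starts at the stay-certain prior (0, 1, 0); the endpoints of
    each changed edge and their immediate neighbors receive the average of
    the role triples they match, renormalized.  Nodes farther than one hop
    from any changed edge keep (0, 1, 0).
    """
    table: dict[str, tuple[float, float, float]] = {
        v: STAY_TRIPLE for v in next_.nodes
    }
    matched: dict[str, list[tuple[float, float, float]]] = {}
    adj = next_.neighbor_map()
    for (u, v), role_u, role_v in _changed_edge_roles(prev, next_, h_prev):
        for node, role in ((u, role_u), (v, role_v)):
            if node in table:
                matched.setdefault(node, []).append(model[role])
        for endpoint in (u, v):
            for nb in sorted(adj.get(endpoint, ())):
                if nb in (u, v) or nb not in h_prev or endpoint not in h_prev:
                    continue
                for psi in classify_relationship(nb, endpoint, next_, h_prev):
                    matched.setdefault(nb, []).append(
                        model[f"neighbor_psi{psi}"]
                    )
    for node, triples in matched.items():
        mean = np.mean(np.asarray(triples), axis=0)
        table[node] = _normalize(mean)
    return table


# ---------------------------------------------------------------------------
# conditional model


def train_conditional(
    net: Network,
    h: Hierarchy,
    N: int,
    M: int,
    rng: np.random.Generator,
    opts: SolverOptions | None = None,
) -> ConditionalModel:
    """Learn the neighbor co-movement conditionals by random perturbation.

    Each of the N rounds picks a uniform random node, forces it to a uniform
    random *different* level, re-solves the rest of the hierarchy exactly
    with that node frozen, and records, for the perturbed node and each of
    its neighbors, the pair of movement classes together with their
    relationship class psi.  Counts are Laplace-smoothed and normalized over
    the movement class of the first argument.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    opts = opts or SolverOptions()
    nodes = sorted(net.nodes)
    adj = net.neighbor_map()
    counts: dict[tuple[int, str], np.ndarray] = {
        (psi, phi): np.zeros(3)
        for psi in range(1, 7)
        for phi in MOVEMENT_CLASSES
    }
    for _ in range(N):
        w = nodes[rng.integers(len(nodes))]
        choices = [l for l in range(1, M + 1) if l != h[w]]
        if not choices:
            continue
        new_level = int(choices[rng.integers(len(choices))])
        res = solve_restricted(
            net,
            M,
            NodeSets.from_dynamic(net, net.nodes - {w}),
            h.updated({w: new_level}),
            opts,
            anchor=True,  # movement = forced by the perturbation, not by
            # arbitrary tie-breaking among degenerate optima
        )
        h2 = res.hierarchy

        def mov(v: str) -> str:
            return classify_movement(h[v], h2[v])

        for u in sorted(adj[w]):
            # both orderings of the pair are informative
            for a, b in ((w, u), (u, w)):
                for psi in classify_relationship(a, b, net, h):
                    counts[(psi, mov(b))][_CLS_INDEX[mov(a)]] += 1
    triples = {key: _normalize(c + 1.0) for key, c in counts.items()}
    return ConditionalModel(triples)


# ---------------------------------------------------------------------------
# score propagation


@dataclass
class MovementScores:
    """Per-node probability triples (down, same, up) after propagation,
    plus the total degree used for rank tie-breaking."""

    x_star: dict[str, tuple[float, float, float]]
    alpha: float
    degree: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False

    def same(self, v: str) -> float:
        return self.x_star[v][1]


def build_system(
    net: Network,
    h_prev: Hierarchy,
    f0: Mapping[str, tuple[float, float, float]],
    cond: ConditionalModel,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble the propagation system x = (1-alpha) A x + alpha b.

    One row per (node, movement class); the block coupling node v to
    neighbor v' carries ``P_psi(v in phi | v' in phi') / |N(v)|`` with psi
    the relationship class of (v, v') under the previous hierarchy (averaged
    when both edge directions exist).  Isolated nodes get an all-zero block
    (their score is the prior alone).  Neighbors without a previous level
    (fresh nodes) contribute nothing.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    order = sorted(net.nodes)
    pos = {v: i for i, v in enumerate(order)}
    n = len(order)
    A = np.zeros((3 * n, 3 * n))
    b = np.zeros(3 * n)
    adj = net.neighbor_map()
    for v in order:
        i = pos[v]
        b[3 * i : 3 * i + 3] = f0.get(v, STAY_TRIPLE)
        nbrs = sorted(adj[v])
        if not nbrs:
            continue
        inv_deg = 1.0 / len(nbrs)
        for u in nbrs:
            if v not in h_prev or u not in h_prev:
                continue
            psis = classify_relationship(v, u, net, h_prev)
            block = np.mean(
                [
                    [
                        [cond[(psi, phi_c)][phi_i] for phi_c in MOVEMENT_CLASSES]
                        for phi_i in range(3)
                    ]
                    for psi in sorted(psis)
                ],
                axis=0,
            )
            j = pos[u]
            A[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block * inv_deg
    return A, b, order


def solve_scores(
    A: np.ndarray,
    b: np.ndarray,
    alpha: float,
    order: Sequence[str],
    degree: Mapping[str, int] | None = None,
) -> MovementScores:
    """Solve the damped propagation system by direct linear solve and
    renormalize each node's triple to sum to 1.

    Each 3x3 neighbor block of A is column-stochastic scaled by 1/|N(v)|,
    so when the incoming triples are (approximately) normalized the
    propagation behaves like a damped averaging and the system is well
    conditioned for moderate alpha; a singular or ill-conditioned system
    raises with the advice to increase alpha.
    """
    n3 = len(order) * 3
    system = np.eye(n3) - (1.0 - alpha) * A
    try:
        x = np.linalg.solve(system, alpha * b)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"propagation system is singular ({err}); increase alpha"
        ) from err
    resid = float(np.max(np.abs(x - ((1.0 - alpha) * A @ x + alpha * b))))
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"propagation residual {resid:.2e} too large; increase alpha"
        )
    x = np.clip(x, 0.0, 1.0)
    scores: dict[str, tuple[float, float, float]] = {}
    degenerate = False
    for i, v in enumerate(order):
        row = x[3 * i : 3 * i + 3]
        s = row.sum()
        if s < 1e-12:
            scores[v] = STAY_TRIPLE
            degenerate = True
        else:
            scores[v] = _normalize(row)
    return MovementScores(
        scores, alpha, dict(degree or {}), degenerate=degenerate
    )


def score_movements(
    prev: Network,
    next_: Network,
    h_prev: Hierarchy,
    models: MovementModels,
) -> MovementScores:
    """End-to-end movement scoring for one transition: prior from the edge
    diff, propagation over the new topology, renormalized triples."""
    f0 = predict_prior(prev, next_, h_prev, models.prior)
    A, b, order = build_system(
        next_, h_prev, f0, models.conditional, models.alpha
    )
    return solve_scores(A, b, models.alpha, order, next_.total_degree())


def rank_nodes(scores: MovementScores) -> list[str]:
    """Nodes in ascending order of their probability to stay put (most
    likely movers first); ties broken by total degree descending, then by
    node identifier."""
    return sorted(
        scores.x_star,
        key=lambda v: (scores.x_star[v][1], -scores.degree.get(v, 0), v),
    )


def select_dynamic(
    ranked: Sequence[str],
    size: int | float,
    new_nodes: Iterable[str] = (),
) -> set[str]:
    """The predicted dynamic node set: all new nodes (their levels are
    unknown, so they must be free) topped up with the highest-ranked movers
    until ``size`` nodes are selected.  ``size`` may be an absolute count or
    a fraction of the ranked list."""
    n = len(ranked)
    if isinstance(size, float) and 0 <= size <= 1:
        k = int(round(size * n))
    else:
        k = int(size)
    if k < 0:
        raise ValueError("size must resolve to a non-negative count")
    k = min(k, n)
    selected = set(new_nodes)
    for v in ranked:
        if len(selected) >= k:
            break
        selected.add(v)
    return selected
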