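"""Incremental decomposition of an evolving network sequence.

The first network's hierarchy is computed exactly (or by divide-and-conquer
above the exact-solve size cap).  Every later network reuses the previous
hierarchy: the movement model predicts which nodes are likely to move, the
predicted dynamic set (plus any brand-new nodes) is re-optimized by the
restricted ILP per connected component, everything else keeps its level.

A no-regression safeguard compares the updated hierarchy against simply
carrying the previous one forward and keeps the better of the two; with a
proven-optimal restricted solve the carried hierarchy can never win (it is
feasible for the restricted problem), so the safeguard matters only when
the solver hits its time limit.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .graph import (
    EvolvingSequence,
    Hierarchy,
    Network,
    NodeSets,
    induced_subgraph,
    penalty,
)
from .ilp import SolverOptions, solve_full
from .ilp import solve_restricted as _solve_restricted
from .movement import (
    MovementModels,
    rank_nodes,
    score_movements,
    select_dynamic,
    train_conditional,
    train_prior,
)
from .baselines import DcConfig, dc_hiden

__all__ = [
    "PipelineConfig",
    "StepReport",
    "initial_hierarchy",
    "step",
    "decompose_sequence",
    "safeguard_no_regression",
    "fit_movement_models",
]

#: above this node count the initial decomposition falls back to
#: divide-and-conquer (the exhaustive solve does not scale past it)
EXACT_INIT_CAP = 100


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the incremental decomposer.

    dynamic_size : absolute node count, or fraction of |V| in (0, 1].
    init_method : "hiden" (exact), "dc-hiden", or "auto" (exact up to
        EXACT_INIT_CAP nodes, divide-and-conquer above).
    """

    max_level: int = 5
    dynamic_size: int | float = 0.2
    alpha: float = 0.5
    init_method: str = "auto"
    solver: SolverOptions = field(default_factory=SolverOptions)
    dc: DcConfig = field(default_factory=DcConfig)
    seed: int = 0
    train_mode: str = "global"
    safeguard: bool = True

    def __post_init__(self) -> None:
        if self.init_method not in ("auto", "hiden", "dc-hiden"):
            raise ValueError(f"unknown init_method {self.init_method!r}")
        if self.train_mode not in ("global", "per_sequence"):
            raise ValueError(f"unknown train_mode {self.train_mode!r}")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class StepReport:
    """Per-transition diagnostics."""

    index: int
    n_dynamic: int
    n_complementary: int
    n_sub_edges: int
    penalty_carried: int
    penalty_after: int
    proven_optimal: bool
    safeguard_triggered: bool
    wall_time: float


def initial_hierarchy(net: Network, cfg: PipelineConfig) -> Hierarchy:
    """Decomposition of the first network in a sequence."""
    method = cfg.init_method
    if method == "auto":
        method = "hiden" if net.n_nodes <= EXACT_INIT_CAP else "dc-hiden"
    if method == "hiden":
        return solve_full(net, cfg.max_level, cfg.solver).hierarchy
    return dc_hiden(net, cfg.max_level, cfg.dc, cfg.solver)


def safeguard_no_regression(
    next_: Network, h_carried: Hierarchy, h_new: Hierarchy
) -> tuple[Hierarchy, bool]:
    """Keep whichever hierarchy scores the lower penalty on the new network
    (ties prefer the fresh solve).  Returns (winner, carried_won)."""
    if penalty(next_, h_carried) < penalty(next_, h_new):
        return h_carried, True
    return h_new, False


def step(
    prev: Network,
    h_prev: Hierarchy,
    next_: Network,
    models: MovementModels,
    cfg: PipelineConfig,
) -> tuple[Hierarchy, StepReport]:
    """One incremental update ``(G_{i-1}, H_{i-1}) -> H_i``."""
    t0 = time.perf_counter()
    M = cfg.max_level
    new_nodes = next_.nodes - prev.nodes

    scores = score_movements(prev, next_, h_prev, models)
    ranked = rank_nodes(scores)
    dyn = select_dynamic(ranked, cfg.dynamic_size, new_nodes)

    levels: dict[str, int] = {}
    n_comp = 0
    n_sub_edges = 0
    proven = True
    for comp in next_.components():
        comp_dyn = dyn & comp.nodes
        if not comp_dyn:
            for v in comp.nodes:
                levels[v] = h_prev[v]
            continue
        sets = NodeSets.from_dynamic(comp, comp_dyn)
        n_comp += len(sets.complementary)
        n_sub_edges += induced_subgraph(comp, sets).n_edges
        res = _solve_restricted(comp, M, sets, h_prev, cfg.solver, anchor=True)
        levels.update(res.hierarchy.level)
        proven &= res.proven_optimal
    h_new = Hierarchy(levels, M)

    # carried-forward alternative: previous levels for surviving nodes, the
    # fresh solve's levels for brand-new ones (which had no previous level)
    carried_levels = {
        v: (h_prev[v] if v in h_prev else h_new[v]) for v in next_.nodes
    }
    h_carried = Hierarchy(carried_levels, M)
    triggered = False
    if cfg.safeguard:
        h_out, triggered = safeguard_no_regression(next_, h_carried, h_new)
    else:
        h_out = h_new

    report = StepReport(
        index=-1,
        n_dynamic=len(dyn),
        n_complementary=n_comp,
        n_sub_edges=n_sub_edges,
        penalty_carried=penalty(next_, h_carried),
        penalty_after=penalty(next_, h_out),
        proven_optimal=proven,
        safeguard_triggered=triggered,
        wall_time=time.perf_counter() - t0,
    )
    return h_out, report


def decompose_sequence(
    seq: EvolvingSequence,
    cfg: PipelineConfig,
    models: MovementModels | None = None,
) -> tuple[list[Hierarchy], list[StepReport]]:
    """Run the incremental decomposer over a whole sequence.

    With ``models=None`` the movement models are trained first: globally on
    a synthetic corpus (default), or on perturbations of the sequence's own
    first network (``train_mode="per_sequence"``).
    """
    if models is None:
        if cfg.train_mode == "per_sequence":
            models = fit_movement_models(
                cfg,
                template=seq[0],
            )
        else:
            models = fit_movement_models(cfg)
    hierarchies = [initial_hierarchy(seq[0], cfg)]
    reports: list[StepReport] = []
    for i in range(1, len(seq)):
        h, rep = step(seq[i - 1], hierarchies[-1], seq[i], models, cfg)
        rep.index = i
        hierarchies.append(h)
        reports.append(rep)
    return hierarchies, reports


# ---------------------------------------------------------------------------
# model training harness


def fit_movement_models(
    cfg: PipelineConfig,
    template: Network | None = None,
    n_pairs: int = 40,
    n_perturbations: int = 150,
    train_nodes: int = 40,
    train_density: float = 2.0,
    mutation_rate: float = 0.1,
) -> MovementModels:
    """Train the prior and conditional movement models on a synthetic corpus.

    Prior: ``n_pairs`` transitions (scale-free network, one mutation step),
    each with both hierarchies solved exactly.  Conditional:
    ``n_perturbations`` forced single-node moves on one training network
    with exact re-solves.  Training networks default to 40 nodes — the local
    movement statistics the models capture do not depend on network size,
    and exact re-solves stay cheap.  With ``template`` given (per-sequence
    mode), mutated copies of the template are used instead of fresh
    generator draws; templates above the exact-solve cap fall back to
    generator draws.
    """
    from .simulate import GeneratorConfig, MutationConfig, generate_scale_free, mutate

    rng = np.random.default_rng(cfg.seed)
    M = cfg.max_level
    opts = cfg.solver

    if template is not None and template.n_nodes <= EXACT_INIT_CAP:
        base_nets = [template] * n_pairs
    else:
        base_nets = [
            generate_scale_free(
                GeneratorConfig(
                    n_nodes=train_nodes,
                    density=train_density,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
            for _ in range(n_pairs)
        ]

    pairs = []
    for net in base_nets:
        mut = MutationConfig(
            rate=mutation_rate, seed=int(rng.integers(2**31 - 1))
        )
        nxt = mutate(net, mut)
        h1 = solve_full(net, M, opts).hierarchy
        # anchor the successor solve on h1: the movement classes then
        # reflect changes forced by the rewiring, not arbitrary
        # tie-breaking among the many penalty-equivalent optima
        h2 = solve_full(nxt, M, opts, anchor=h1).hierarchy
        pairs.append((net, nxt, h1, h2))
    prior = train_prior(pairs)

    cond_net = base_nets[0]
    cond_h = solve_full(cond_net, M, opts).hierarchy
    conditional = train_conditional(
        cond_net, cond_h, n_perturbations, M, rng, opts
    )
    return MovementModels(
        prior,
        conditional,
        alpha=cfg.alpha,
        n_perturbations=n_perturbations,
        seed=cfg.seed,
    )
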