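"""Quality measures and simulation-experiment harnesses.

The single quality objective everywhere is the penalty (number of
conflicting edges).  For the incremental decomposer, quality relative to
the exhaustive optimum is summarized by

    accuracy = (1 + penalty_exhaustive) / (1 + penalty_candidate)

which lies in (0, 1] whenever the reference solve is proven optimal (the
+1 regularization keeps conflict-free instances well defined).

Experiment harnesses reproduce the package's standard simulation studies —
method comparison on mutated networks, sweeps over density / node count /
level count / dynamic-set fraction / propagation weight alpha, and
multi-step error-propagation runs — at configurable replicate counts, and
emit tidy per-replicate DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import DcConfig, bfs_hierarchy, dc_hiden, hino, vertex_sort
from .graph import Hierarchy, penalty
from .ilp import SolverOptions, solve_full
from .movement import MovementModels
from .pipeline import (
    PipelineConfig,
    decompose_sequence,
    fit_movement_models,
    initial_hierarchy,
    step,
)
from .simulate import GeneratorConfig, MutationConfig, generate_sequence

__all__ = [
    "accuracy",
    "MovementSummary",
    "movement_summary",
    "run_experiment",
    "EXPERIMENTS",
]


def accuracy(penalty_reference: int, penalty_candidate: int) -> float:
    """``(1 + penalty_reference) / (1 + penalty_candidate)``."""
    if penalty_reference < 0 or penalty_candidate < 0:
        raise ValueError("penalties must be non-negative")
    return (1 + penalty_reference) / (1 + penalty_candidate)


@dataclass
class MovementSummary:
    """Movement classification of nodes across a hierarchy sequence plus
    per-network level occupancy histograms."""

    move_up: int
    move_down: int
    stay_same: int
    fluctuate: int
    per_node: dict[str, str]
    level_histograms: list[dict[int, int]]

    @property
    def total(self) -> int:
        return self.move_up + self.move_down + self.stay_same + self.fluctuate


def movement_summary(hierarchies: list[Hierarchy]) -> MovementSummary:
    """Classify every node present in all hierarchies of a sequence.

    "stay same" — level constant throughout; "move up"/"move down" — all
    level changes weakly monotone in one direction with at least one strict
    change; "fluctuate" — at least one strict rise AND one strict fall
    (the only reading under which the four classes partition the nodes).
    """
    if len(hierarchies) < 2:
        raise ValueError("need at least two hierarchies")
    shared = set(hierarchies[0].level)
    for h in hierarchies[1:]:
        shared &= set(h.level)
    per_node: dict[str, str] = {}
    counts = {"move_up": 0, "move_down": 0, "stay_same": 0, "fluctuate": 0}
    for v in sorted(shared):
        traj = [h[v] for h in hierarchies]
        diffs = [b - a for a, b in zip(traj, traj[1:])]
        rises = any(d > 0 for d in diffs)
        falls = any(d < 0 for d in diffs)
        if rises and falls:
            cls = "fluctuate"
        elif rises:
            cls = "move_up"
        elif falls:
            cls = "move_down"
        else:
            cls = "stay_same"
        per_node[v] = cls
        counts[cls] += 1
    histograms = []
    for h in hierarchies:
        hist = {l: 0 for l in range(1, h.max_level + 1)}
        for v in h:
            hist[h[v]] += 1
        histograms.append(hist)
    return MovementSummary(
        counts["move_up"],
        counts["move_down"],
        counts["stay_same"],
        counts["fluctuate"],
        per_node,
        histograms,
    )


# ---------------------------------------------------------------------------
# experiment harnesses


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def _two_step_sequence(n_nodes, density, rate, rng):
    gen = GeneratorConfig(n_nodes=n_nodes, density=density, seed=_spawn_seed(rng))
    mut = MutationConfig(rate=rate, seed=_spawn_seed(rng))
    return generate_sequence(gen, 2, mut)


def experiment_method_comparison(
    n_nodes: int = 100,
    density: float = 2.0,
    M: int = 5,
    rate: float = 0.1,
    n_replicates: int = 20,
    dynamic_size: int | float = 50,
    seed: int = 0,
    models: MovementModels | None = None,
    solver: SolverOptions | None = None,
    include_exhaustive: bool = False,
) -> pd.DataFrame:
    """Penalty comparison of all methods on mutated scale-free networks.

    Per replicate: generate G1, mutate once to G2, give the incremental
    method the initial decomposition of G1 (divide-and-conquer above the
    exact cap), and score every method's hierarchy of G2.
    """
    rng = np.random.default_rng(seed)
    cfg = PipelineConfig(
        max_level=M,
        dynamic_size=dynamic_size,
        seed=seed,
        solver=solver or SolverOptions(),
        dc=DcConfig(seed=seed),
    )
    if models is None:
        models = fit_movement_models(cfg)
    records = []
    for rep in range(n_replicates):
        seq = _two_step_sequence(n_nodes, density, rate, rng)
        g1, g2 = seq[0], seq[1]
        h1 = initial_hierarchy(g1, cfg)
        h2, _ = step(g1, h1, g2, models, cfg)
        rows = {
            "d-hiden": penalty(g2, h2),
            "dc-hiden": penalty(
                g2, dc_hiden(g2, M, DcConfig(seed=_spawn_seed(rng)), cfg.solver)
            ),
            "bfs": penalty(g2, bfs_hierarchy(g2, M)),
            "vertex-sort": penalty(g2, vertex_sort(g2, M)[1]),
            "hino": penalty(g2, hino(g2, M)),
        }
        if include_exhaustive:
            rows["hiden"] = solve_full(g2, M, cfg.solver).objective
        for method, pen in rows.items():
            records.append(
                {
                    "replicate": rep,
                    "method": method,
                    "n_nodes": n_nodes,
                    "density": density,
                    "M": M,
                    "penalty": pen,
                }
            )
    return pd.DataFrame.from_records(records)


def experiment_fraction_sweep(
    n_nodes_values=(50,),
    density_values=(2.0,),
    M_values=(5,),
    fractions=(0.1, 0.2, 0.4, 0.6, 0.8),
    rate: float = 0.1,
    n_replicates: int = 20,
    seed: int = 0,
    models: MovementModels | None = None,
    solver: SolverOptions | None = None,
) -> pd.DataFrame:
    """Accuracy of the incremental method vs the exhaustive optimum over a
    grid of network parameters and dynamic-set fractions.

    One replicate = one (G1, G2) transition; the exhaustive reference and
    every fraction share it, so accuracies are paired across fractions.
    """
    rng = np.random.default_rng(seed)
    solver = solver or SolverOptions()
    base_cfg = PipelineConfig(max_level=5, seed=seed, solver=solver)
    if models is None:
        models = fit_movement_models(base_cfg)
    records = []
    for n_nodes in n_nodes_values:
        for density in density_values:
            for M in M_values:
                cfg = PipelineConfig(
                    max_level=M, seed=seed, solver=solver, init_method="hiden"
                )
                for rep in range(n_replicates):
                    seq = _two_step_sequence(n_nodes, density, rate, rng)
                    g1, g2 = seq[0], seq[1]
                    h1 = solve_full(g1, M, solver).hierarchy
                    ref = solve_full(g2, M, solver)
                    for frac in fractions:
                        cfg_f = PipelineConfig(
                            max_level=M,
                            dynamic_size=frac,
                            seed=seed,
                            solver=solver,
                        )
                        h2, rep_info = step(g1, h1, g2, models, cfg_f)
                        records.append(
                            {
                                "replicate": rep,
                                "n_nodes": n_nodes,
                                "density": density,
                                "M": M,
                                "fraction": frac,
                                "penalty_dhiden": penalty(g2, h2),
                                "penalty_hiden": ref.objective,
                                "accuracy": accuracy(
                                    ref.objective, penalty(g2, h2)
                                ),
                                "n_dynamic": rep_info.n_dynamic,
                            }
                        )
    return pd.DataFrame.from_records(records)


def experiment_multi_step(
    n_nodes: int = 50,
    density: float = 2.0,
    M: int = 5,
    K: int = 25,
    rate: float = 0.1,
    n_sequences: int = 20,
    dynamic_size: int | float = 0.2,
    reference: str = "hiden",
    seed: int = 0,
    models: MovementModels | None = None,
    solver: SolverOptions | None = None,
    dc_subnet: int = 50,
) -> pd.DataFrame:
    """Error propagation over long evolving sequences.

    The incremental method runs once down each sequence; the reference
    method ("hiden" exhaustive or "dc-hiden") is re-run from scratch at
    every step.  Emits per (sequence, step) penalties and the relative
    excess penalty of the incremental method.
    """
    if reference not in ("hiden", "dc-hiden"):
        raise ValueError("reference must be 'hiden' or 'dc-hiden'")
    rng = np.random.default_rng(seed)
    solver = solver or SolverOptions()
    init = "hiden" if reference == "hiden" else "dc-hiden"
    cfg = PipelineConfig(
        max_level=M,
        dynamic_size=dynamic_size,
        seed=seed,
        solver=solver,
        init_method=init,
        dc=DcConfig(subnet_size=dc_subnet, seed=seed),
    )
    if models is None:
        models = fit_movement_models(cfg)
    records = []
    for s in range(n_sequences):
        gen = GeneratorConfig(
            n_nodes=n_nodes, density=density, seed=_spawn_seed(rng)
        )
        mut = MutationConfig(rate=rate, seed=_spawn_seed(rng))
        seq = generate_sequence(gen, K, mut)
        hs, _ = decompose_sequence(seq, cfg, models)
        for i in range(1, K):
            g = seq[i]
            pen_d = penalty(g, hs[i])
            if reference == "hiden":
                pen_ref = solve_full(g, M, solver).objective
            else:
                pen_ref = penalty(
                    g,
                    dc_hiden(
                        g,
                        M,
                        DcConfig(subnet_size=dc_subnet, seed=_spawn_seed(rng)),
                        solver,
                    ),
                )
            records.append(
                {
                    "sequence": s,
                    "step": i,
                    "penalty_dhiden": pen_d,
                    "penalty_reference": pen_ref,
                    "reference": reference,
                    "rel_excess": (pen_d - pen_ref) / pen_ref
                    if pen_ref > 0
                    else np.nan,
                }
            )
    return pd.DataFrame.from_records(records)


def experiment_alpha_sweep(
    alphas=(0.1, 0.3, 0.5, 0.7, 0.9),
    n_nodes: int = 50,
    density: float = 2.0,
    M: int = 5,
    rate: float = 0.1,
    fraction: float = 0.2,
    n_replicates: int = 10,
    seed: int = 0,
    solver: SolverOptions | None = None,
) -> pd.DataFrame:
    """Sensitivity of the incremental method's accuracy to the propagation
    weight alpha (prior weight in the score fixed point)."""
    rng = np.random.default_rng(seed)
    solver = solver or SolverOptions()
    records = []
    base_cfg = PipelineConfig(max_level=M, seed=seed, solver=solver)
    models = fit_movement_models(base_cfg)
    transitions = []
    for _ in range(n_replicates):
        seq = _two_step_sequence(n_nodes, density, rate, rng)
        g1, g2 = seq[0], seq[1]
        h1 = solve_full(g1, M, solver).hierarchy
        ref = solve_full(g2, M, solver).objective
        transitions.append((g1, g2, h1, ref))
    for alpha in alphas:
        m = MovementModels(
            models.prior,
            models.conditional,
            alpha=alpha,
            n_perturbations=models.n_perturbations,
            seed=models.seed,
        )
        cfg = PipelineConfig(
            max_level=M,
            dynamic_size=fraction,
            alpha=alpha,
            seed=seed,
            solver=solver,
        )
        for rep, (g1, g2, h1, ref) in enumerate(transitions):
            h2, _ = step(g1, h1, g2, m, cfg)
            records.append(
                {
                    "replicate": rep,
                    "alpha": alpha,
                    "penalty_dhiden": penalty(g2, h2),
                    "penalty_hiden": ref,
                    "accuracy": accuracy(ref, penalty(g2, h2)),
                }
            )
    return pd.DataFrame.from_records(records)


EXPERIMENTS = {
    "method-comparison": experiment_method_comparison,
    "density-sweep": lambda **kw: experiment_fraction_sweep(
        density_values=kw.pop("density_values", (1.0, 2.0, 3.0)), **kw
    ),
    "node-count-sweep": lambda **kw: experiment_fraction_sweep(
        n_nodes_values=kw.pop("n_nodes_values", (30, 50, 70)), **kw
    ),
    "level-count-sweep": lambda **kw: experiment_fraction_sweep(
        M_values=kw.pop("M_values", (3, 5, 10)), **kw
    ),
    "multi-step-large": lambda **kw: experiment_multi_step(
        n_nodes=kw.pop("n_nodes", 500),
        reference=kw.pop("reference", "dc-hiden"),
        **kw,
    ),
    "multi-step-small": lambda **kw: experiment_multi_step(
        n_nodes=kw.pop("n_nodes", 50),
        reference=kw.pop("reference", "hiden"),
        **kw,
    ),
    "alpha-sweep": experiment_alpha_sweep,
}


def run_experiment(name: str, **kwargs) -> pd.DataFrame:
    """Dispatch a named experiment; see ``EXPERIMENTS`` for choices."""
    try:
        fn = EXPERIMENTS[name]
    except KeyError:
        raise ValueError(
            f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}"
        ) from None
    return fn(**kwargs)
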