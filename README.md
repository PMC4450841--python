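# dhiden

Incremental hierarchical decomposition of dynamically evolving gene
regulatory networks.

## The problem

A gene regulatory network is a directed graph `G = (V, E)` whose nodes are
genes (or their products) and whose edges are regulatory interactions.  A
*hierarchical decomposition* assigns every gene one of `M` integer levels,
`H : V → {1, …, M}`, with master regulators at the top (`M`) and terminal
targets at the bottom (`1`).  Regulation should flow downward: an edge
`(u, v)` is **conflicting** when `H(u) ≤ H(v)`, and the quality of a
decomposition is its **penalty**

```
P_G(H) = |{ (u, v) ∈ E : H(u) ≤ H(v) }|
```

Finding the minimum-penalty decomposition is an integer linear program
(here: one level variable per node, one binary conflict indicator per edge,
constraint `t_u − t_v + ε_uv·M ≥ 1`), solved exactly by the HiGHS MILP
backend of `scipy.optimize.milp`.

Real regulatory networks rewire over time — during development, between
cell types, under perturbation.  Re-solving the ILP from scratch after
every small change is wasteful and quickly intractable.  This package
implements an *incremental* decomposer: after a topology change it predicts
which nodes are likely to change level (the **dynamic node set** `D`),
freezes everything else at its previous level, and re-optimizes only the
subgraph induced by `D` and its frozen one-hop boundary.

The prediction is a learned probabilistic model.  Each node gets a triple
`(P(down), P(same), P(up))` obtained by solving the damped propagation
fixed point

```
x = (1 − α) A x + α b        ⇒        x* = (I − (1 − α) A)⁻¹ α b
```

where `b` stacks per-node priors driven by proximity to inserted/deleted
edges and `A` carries learned neighbor co-movement conditionals
`P_ψ(v ∈ φ | u ∈ φ′)` indexed by the six relationship classes ψ (direction
of the connecting edge × relative level order).  Nodes are ranked by
ascending `P(same)`; the top of the ranking becomes the dynamic set.

Five static baselines are included for comparison: BFS levels, vertex-sort
(topological sort of the SCC condensation, with level ranges), HINO
(BFS plus downgrade/upgrade corrections), the exhaustive ILP, and a
divide-and-conquer ILP that covers large networks with locally exact
solves.

Intended users: computational biologists studying regulatory hierarchy and
its rewiring, and anyone needing fast minimum-violation level assignments
on evolving directed networks.

## Worked example

```python
from dhiden import (GeneratorConfig, MutationConfig, generate_sequence,
                    DynamicHierarchyModel)

seq = generate_sequence(GeneratorConfig(n_nodes=50, density=2, seed=11),
                        K=5, mut=MutationConfig(rate=0.1, seed=12))
res = DynamicHierarchyModel(seq, max_level=5, dynamic_size=0.2,
                            seed=0).fit()
print(res.summary())
```

prints (training the movement models takes ~1 minute the first time):

```
Incremental hierarchy decomposition
============================================
sequence length:   5
max level (M):     5
dynamic size:      0.2
alpha:             0.5
penalty by step:   [15, 17, 18, 19, 19]
mean penalty:      17.60
safeguard hits:    0
```

The first penalty (15) is the exhaustive optimum of the first network; each
later value is achieved by re-optimizing only ten predicted nodes (20% of
50) per step.  For reference, fresh exhaustive solves of the five networks
give penalties 15, 17, 16, 17, 17 — the incremental method pays one or two
extra conflicts for updating a small fraction of the network instead of
all of it.

The same run from the shell:

```bash
dhiden simulate --nodes 50 --density 2 --steps 5 --rate 0.1 --seed 11 --out seq/
dhiden decompose --sequence seq/manifest.json --method d-hiden \
    --dynamic-size 0.2 --out out/
dhiden penalty --net seq/net_004.tsv --hierarchy out/hierarchy_004.tsv
```

Single static networks work through `HierarchyModel`:

```python
from dhiden import HierarchyModel, read_edge_list
net = read_edge_list("seq/net_000.tsv")
print(HierarchyModel(net, max_level=5).fit(method="hiden").summary())
```

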