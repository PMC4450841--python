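# Methods

## Model and objective

A regulatory network is a directed graph over named genes; a hierarchical
decomposition is a total map `H : V → {1, …, M}` with `M` the top level.
Edge `(u, v)` conflicts when `H(u) ≤ H(v)` (equality counts: regulation
must flow strictly downward), and the penalty of `H` is the number of
conflicting edges — the only quality objective used anywhere in the
package.  Self-loops are dropped at construction: they conflict under
every possible `H`, so they would add the same constant to every penalty
and carry no information about the decomposition.  Edge multiplicity is
not modeled; duplicate input edges collapse.  Connectivity is defined on
the direction-enriched graph (the edges plus all their reversals), and all
solvers work per connected component — components share no edges, so their
optima are independent.

## Exact solver

The minimum-penalty decomposition is a MILP: level `t_u ∈ {1..M}` per
node, binary conflict indicator `ε_uv` per edge, objective `Σ ε_uv`,
constraint `t_u − t_v + ε_uv·M > 0` encoded integer-safely as `≥ 1`.
Backend: `scipy.optimize.milp` (HiGHS), single-threaded, deterministic for
a fixed input; node and edge orders are sorted before building the model.

Two equivalent encodings are provided (`SolverOptions.formulation`).  The
direct "level" encoding above has a weak linear relaxation (fractional
`ε ≈ (1 − t_u + t_v)/M` lets the LP pretend away conflicts), and
branch-and-bound on cyclic networks stalls — we measured up to ~80 s on
single 100-node, density-2 instances.  The default "assignment" encoding
uses binaries `y[v, l]` with `Σ_l y[v, l] = 1` and, per edge and level
`l`, the threshold constraint
`ε_uv ≥ Σ_{l′≤l} y[u, l′] + Σ_{l′≥l} y[v, l′] − 1`.
The integer feasible sets coincide (the test suite asserts equal optima of
both encodings against exhaustive enumeration), but the relaxation is much
tighter; the same 100-node instances solve in 1–5 s and 50-node instances
in ~0.1–1 s.  Default solver options: 600 s time limit, optimality gap 0.

### Stability anchoring

The optimum is massively degenerate: typical instances admit many
penalty-equal decompositions, and an unconstrained solver returns an
arbitrary one.  Comparing two independently solved optima of two nearly
identical networks then marks a large, essentially random share of nodes
(30–60% in our 50-node simulations) as "moved" — which would make
movement both unlearnable and meaningless.  Wherever a previous hierarchy
exists, the solver therefore breaks ties toward it: each anchored node's
`y[v, H_prev(v)]` earns a reward of `1/(n_free + 1)` in the objective, so
the total reward stays below one conflict and conflict minimization
remains lexicographically first.  Among all penalty-optimal solutions the
solver thus returns one moving the fewest nodes.  Anchoring is used when
solving the successor network of a training pair, in the perturbation
re-solves of conditional-model training, and in the pipeline's restricted
updates; plain (unanchored) solves remain the reference in all evaluation
harnesses.

## Restricted (incremental) solve

Given the previous hierarchy and a dynamic node set `D`, every node
outside `D` keeps its level verbatim; the solver sees only the subgraph
induced by `D` and its complementary boundary `C` (non-dynamic nodes with
an edge to `D`), with `C` frozen.  Edges between two frozen nodes are a
constant and are removed from the objective.  Since the carried-forward
hierarchy is itself feasible for this problem, a proven-optimal restricted
solve can never be worse than not updating; a no-regression safeguard
(active by default, relevant only after solver timeouts) additionally
compares against the carried hierarchy and keeps the better.

## Movement model

Movement classes: down / same / up between two hierarchies.  Relationship
classes ψ1–ψ6 between an ordered node pair: direction of the connecting
edge × relative level order (above / equal / below), one class per edge
direction for mutually connected pairs.

**Prior.**  Learned from a corpus of (network, mutated network) pairs with
both hierarchies solved exactly (successor anchored).  For every changed
edge, the movement of its endpoints and of their one-hop neighbors is
counted per node role, counts are Laplace-smoothed (add one) and
normalized.  The role taxonomy is a declared reconstruction: endpoint
roles are source/target × inserted/deleted × the changed edge's relative
previous level order (above/equal/below), and neighbor roles are indexed
by the relationship class ψ to the changed endpoint — 18 roles in total.
The level-order conditioning is what makes the prior informative: an
inserted edge that already points downhill forces nothing, while an
inserted uphill edge must either move its endpoints or pay a conflict.
A coarser taxonomy (source/target × inserted/deleted + one neighbor
class) left the ranking statistically indistinguishable from random
ordering in our simulations.

At prediction time every node starts from the stay-certain prior
`(0, 1, 0)`; nodes matching roles of the actual edge diff receive the
average of their matched role triples, renormalized (order-independent
and idempotent).  Nodes farther than one hop from every changed edge keep
`(0, 1, 0)` — locality is asserted as a test invariant.

**Conditional.**  `P_ψ(v ∈ φ | u ∈ φ′)` is learned by repeatedly (default
N = 150) forcing a uniformly chosen node to a uniformly chosen different
level, re-solving the rest exactly with that node frozen (anchored), and
recording, for the perturbed node and each neighbor, both orderings of
(ψ under the pre-perturbation hierarchy, the two movement classes).
Counts are Laplace-smoothed per (ψ, conditioning class).

**Propagation.**  Scores solve `x = (1 − α) A x + α b` by direct linear
solve; `A`'s 3×3 block coupling node v to neighbor v′ is the ψ-conditional
(averaged when both edge directions exist) scaled by `1/|N(v)|`; isolated
nodes have zero blocks and keep their prior.  The fixed-point residual is
checked (`< 1e−8`) and each node's triple is renormalized before ranking,
because `A` is not exactly row-stochastic.  `α` (default 0.5; no canonical
value exists) balances prior against neighborhood; an α-sweep harness is
included in the evaluation module.  Ranking is by
ascending stay-probability with ties broken by total degree (descending)
then node id; the dynamic set is the top of the ranking, with all
brand-new nodes always included (they have no previous level to freeze).

Training defaults: 40 prior pairs and one conditional network, all of
40 nodes at density 2 — the statistics are local and do not depend on
network size, and exact re-solves at this size cost ~0.1 s each, keeping
full training around a minute on one CPU.

## Synthetic evolving networks

Initial networks grow by preferential attachment: a short chain seed of
`⌈density⌉ + 1` nodes, then each new node attaches to ~`density` distinct
existing nodes (drawn from the edge-endpoint multiset, with a 10% uniform
exploration component so early nodes do not absorb everything);
non-integer densities alternate attachment counts between floor and
ceiling.  Each new edge initially points from the new node to the chosen
target and is flipped with probability 0.5: a pure new→old orientation
would make every generated network acyclic and the decomposition problem
trivially conflict-free at sufficient depth, unlike real regulatory
networks.  Evolution applies `⌈r·|E|/2⌉` degree-preserving swaps per step
(default rate r = 0.1): two node-disjoint edges `(u1,v1), (u2,v2)` become
`(u1,v2), (u2,v1)`; swaps creating self-loops or duplicates are rejected
and re-drawn (up to 100·|E| attempts).  Every in- and out-degree is
preserved exactly — asserted as a test invariant.  All generation flows
from explicit integer seeds; identical seeds give bit-identical sequences.

What this emulates: bounded edge churn on a heavy-tailed directed
topology, the regime in which incremental updating is meaningful.  What it
does not emulate: signed/weighted regulation, correlated or modular
rewiring, duplication-divergence growth, hub-biased interaction loss, or
measurement noise.  Passing tests therefore demonstrate correctness of the
algorithms and their relative ordering under this null-like rewiring
model, not performance on any particular real regulatory dataset (a
plain-TSV loader is provided for applying the method to real edge lists).

## Baselines

* **BFS** — levels by breadth-first distance from the zero-in-degree
  roots, `level = M − min(d, M−1)`; rootless (cyclic) components fall back
  to the maximum-out-degree node, and nodes unreachable along edge
  direction go to the bottom level.  These conventions are ours; the
  method is known to have no mechanism for cycles.
* **Vertex-sort** — contract strongly connected components, topologically
  sort, give each condensation vertex the interval [1 + longest path to a
  sink, L − longest path from a source] rescaled monotonically into 1..M;
  all members of an SCC share the interval.  The method natively returns
  ranges; penalties are computed at the interval midpoint (rounded up).
* **HINO** — BFS start, then iterated corrections to a fixed point (cap
  2·M sweeps): *downgrade* sets each node's level to the minimum over
  itself and its regulators (one reading of an ambiguous rule, flagged
  here); *upgrade* raises a node one level if it regulates a same-level
  node and has no regulator itself.
* **Divide-and-conquer ILP** — grow a BFS ball (≤ 50 nodes by default) on
  the enriched graph around a random unassigned node, solve it exactly
  with already-assigned boundary nodes frozen, repeat until total; an
  optional refinement phase re-optimizes random balls and can only lower
  the penalty.  Refinement is off by default: the original scheme this
  reconstructs is a single cover-and-merge, and the refined variant is
  strong enough to blur the quality gap the incremental method is being
  measured against.  The merging details of the original are unpublished,
  so all comparisons against this baseline are directional.

## Evaluation harnesses and problem sizes

Accuracy is `(1 + penalty_exhaustive)/(1 + penalty_candidate)`, in (0, 1]
when the reference is proven optimal.  Movement summaries classify each
node across a hierarchy sequence as stay-same / move-up / move-down
(weakly monotone with ≥ 1 strict change) / fluctuate (≥ 1 strict rise and
≥ 1 strict fall) — the only reading that makes the four classes a
partition — plus per-network level occupancy histograms.

The experiment harnesses (method comparison, density / node-count /
level-count sweeps over dynamic-set fractions, multi-step error
propagation, α sweep) emit tidy per-replicate DataFrames and are
replayable from their seeds.  Default replicate counts are sized for a
desk-scale run on one CPU; the headline numbers use: accuracy at a 20%
dynamic set — 60 transitions pooled over 30/50/70 nodes; multi-step
excess vs fresh exact solves — 30 sequences of 25 steps at 50 nodes
(8 sequences in the test suite); multi-step comparison against
divide-and-conquer — 4 sequences of 20 steps at 200 nodes with a 50-node
dynamic set.  These sizes are deliberate desk-scale choices; the reported
means are stable at this scale, but individual replicates are noisy, and
larger replicate counts tighten them further.

## Known limitations

* The helper listings of the movement-training algorithms are not public;
  the role taxonomy, smoothing, and normalization here are reconstructions
  (declared above), and the divide-and-conquer merging scheme likewise.
* The restricted update freezes mispredicted nodes at stale levels; errors
  can persist until a later change touches their neighborhood.  The
  multi-step excess stabilizes (~25–35% above fresh exact solves in the
  50-node regime) rather than vanishing.
* `α`, the training corpus size, and the perturbation count N are not
  identifiable from the source material; defaults are stated above and
  exposed in configuration.
* Wall-clock comparisons between methods are environment-dependent and are
  not asserted anywhere; only penalty orderings are.
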