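# netprio

Network-propagation prioritization of disease susceptibility genes on a
heterogeneous multi-layer molecular network, with drug repositioning by
target-set enrichment.

## The problem

For many diseases only a handful of susceptibility genes (SGs) are
experimentally verified, while the regulatory context — lncRNA–mRNA,
miRNA–target, TF–target and protein–protein interactions — is catalogued in
public databases. `netprio` is for computational biologists who want to turn
those two resources into a ranked list of candidate genes: it merges the
interaction layers into one heterogeneous network over typed molecular nodes
(mRNA, miRNA, lncRNA, TF, protein), then propagates risk from the known SGs
by guilt-by-association.

## The model

Risk diffuses by random walk with restart (RWR). With `W` the
column-normalized adjacency matrix of the merged network (m nodes) and
`RG_0` the seed vector putting mass 1/n on each of the n seed genes,

    RG_t = r · W · RG_{t-1} + (1 − r) · RG_0

is iterated to its steady state; `r ∈ (0, 1)` is the restart probability
(default 0.4). Because `W` is column-stochastic, the fixed point
`x = (1 − r)(I − rW)^{-1} RG_0` exists and the iteration contracts in L1 at
rate `r`; `solve_direct` computes it exactly and backs the iterative solver
as an oracle. `r` is tuned by leave-one-out cross-validation: each seed is
held out in turn, the walk runs from the remaining n − 1 seeds, and the
pooled per-trial rankings give a ROC curve over rank thresholds whose AUC
scores the parameter. With all seeds in place, the top-k non-seed nodes
(k = 50 by default) are the candidate SGs; their induced subnetwork is
profiled (density, mean distance in the background network, betweenness),
and each drug's target set is tested for overlap with the candidates by the
exact upper hypergeometric tail P(X ≥ k), Benjamini–Hochberg adjusted
across drugs.

A synthetic-fixture module generates multi-layer networks with a planted
cross-layer module (elevated within-module edge probability `p_in` against
background `p_out`) and a drug-target table with one planted enriched drug,
so the whole pipeline is testable without any database exports.

## Worked example

```python
from netprio import *

spec = SyntheticSpec(rng_seed=0)          # 300 typed nodes, 20-node planted module
fixture = generate_multilayer_network(spec)
network = fixture.assemble()
print(f"network: {network.m} nodes, {network.edge_count} edges")

matrix = build_transition_matrix(network)
seeds = SeedSet.from_nodes(matrix, fixture.seeds)

sweep = sweep_restart(matrix, seeds, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
print(f"best r = {sweep.best_r}, AUC = {dict(sweep.grid)[sweep.best_r]:.4f}")

ranked = rank_genome_wide(matrix, seeds, RestartConfig(r=sweep.best_r))
top = select_top_k(ranked, 50)
print(f"top-50 tallies: {top.type_tallies}")

summary = summarize_topology(network, top.nodes)
print(f"candidate subnetwork: {summary.induced_nodes} nodes, "
      f"{summary.induced_edges} edges, density {summary.density:.3f}, "
      f"mean distance {summary.mean_distance:.2f}")
```

prints

```
network: 228 nodes, 259 edges
best r = 0.3, AUC = 0.7954
top-50 tallies: {'protein': 3, 'miRNA': 11, 'TF': 8, 'mRNA': 20, 'lncRNA': 8}
candidate subnetwork: 50 nodes, 43 edges, density 0.035, mean distance 3.85
```

Only 228 of the 300 declared nodes carry edges at the sparse background
rate, so the merged network has 228 nodes. The cross-validated AUC of
0.80 (against ≈ 0.45 for permuted seeds) shows the walk retrieves held-out
planted-module genes far better than chance; the candidate list spans all
five molecule types, and the candidates sit closer together in the network
(mean distance 3.85) than random sets of equal size.

The same workflow is scriptable from a shell via the `netprio` console
command (`simulate`, `build`, `propagate`, `loocv`, `sweep`, `rank`,
`drugs`, `topology`); every stage writes TSV tables plus a `manifest.json`,
and reruns with the same inputs and `--rng-seed` are byte-identical. Real
analyses substitute database exports (tab-separated edge tables per layer
and a seed-gene list) for the simulated fixture.

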