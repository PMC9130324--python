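# Methods

## Network model

The analysis object is an undirected, unweighted heterogeneous network over
typed molecular nodes. Nodes are `(identifier, node_type)` pairs with
`node_type ∈ {mRNA, miRNA, lncRNA, TF, protein, unknown}`; keeping the type
in the key means a miRNA and a gene that share a raw string remain distinct
nodes. Identifier normalization is deterministic and idempotent: strip
whitespace, lower-case miRNA names (`hsa-miR-200c → hsa-mir-200c`),
upper-case gene/protein/TF/lncRNA symbols. Layers (lncRNA–mRNA, miRNA–mRNA,
miRNA–lncRNA, TF–miRNA, TF–mRNA, PPI, or any user-labelled table) are
merged by union; duplicate undirected edges collapse to a single edge whose
layer provenance is retained as a set. Regulatory layers are biologically
directed, but the walk needs bidirectional reachability for
guilt-by-association, so all layers are symmetrized — the standard choice
in propagation-based prioritization. Self-loops are rejected at parse time
(they would distort the column normalization), and the node set is the
union of edge endpoints, so isolated nodes cannot occur.

## Propagation

The walk matrix is the column-normalized adjacency, `W = A D^{-1}`: column
j spreads a walker at node j uniformly over its neighbors. A raw 0/1
adjacency would make the iteration diverge whenever `r·ρ(A) ≥ 1`;
normalization makes `W` column-stochastic, so the steady state is a
probability vector. The update

    RG_t = r · W · RG_{t-1} + (1 − r) · RG_0

starts from the seed vector (`1/n` per seed) and stops when the L1 change
falls below `tol` (default 1e-10, `max_iter` 1000). The iteration contracts
at rate `r`, so ~`log(tol)/log(r)` iterations suffice; non-convergence is a
warning, not an error, and the last iterate is used. `solve_direct`
computes the exact fixed point `(1 − r)(I − rW)^{-1} RG_0` with a sparse LU
solve; the system is non-singular for every `r < 1` because `ρ(W) = 1`. In
tests the two routes agree to 1e-8 L1, and score comparisons use absolute
tolerance 1e-8 throughout.

Seeds that fail to map into the network are dropped with a warning and the
`1/n` weights recomputed over the mapped remainder, so cross-validation
proceeds even when identifier mapping is imperfect.

One caveat on interpreting scores: proximity to the seeds decays with
distance, but the seed itself need not outrank its own neighbor at high
`r` — with little restart mass, a degree-1 seed on a path scores below its
degree-2 neighbor. Decay with distance is guaranteed only from distance 1
outward.

## Cross-validation and the restart sweep

Leave-one-out: each seed in turn is held out, the walk runs from the
remaining `n − 1` seeds reweighted to `1/(n − 1)`, and all nodes except
those trial seeds — the held-out gene included — are ranked by descending
score. Ties in score are broken by `(identifier, node_type)` lexicographic
order, making every ranking deterministic. The n per-trial lists are pooled
on the rank scale (trial score scales differ, rank thresholds do not): at
threshold k, TPR is the fraction of held-out genes with rank ≤ k and FPR
the fraction of pooled non-held-out candidates with rank ≤ k, one threshold
per achievable rank, AUC by trapezoid. When a trial has no non-held-out
candidates (degenerate two-node fixtures) FPR is defined as 0 and the curve
closes at (1, 1). The restart sweep repeats the full LOOCV at each grid
value of `r` and returns the argmax, ties broken toward smaller `r`.

## Ranking and drug enrichment

Genome-wide ranking is one propagation from the full seed set; seeds are
excluded from the output (the workflow predicts novel genes; a diagnostic
flag re-includes them), unreachable nodes keep score 0 and stay at the
bottom so list length is stable, and the top k = 50 form the candidate set.

Drug repositioning tests each drug's target set for overlap with the
candidates using the exact upper hypergeometric tail `P(X ≥ k)` for
`X ~ Hypergeom(N, K, n_c)`. The default universe N is the set of network
nodes targeted by at least one drug in the supplied tables — candidate
membership should be compared against genes that *could* have been drawn as
targets — with an "all network nodes" option. Drugs with no in-universe
target are skipped. P-values are Benjamini–Hochberg adjusted across the
tested drugs (the correction choice is a package decision; raw and adjusted
values are both reported) and significance is called at adjusted p ≤ α
(default 0.05). Combination products ("carboplatin + docetaxel") are single
drug ids.

## Topology

The candidate subnetwork is the induced subgraph; density is
`2E/(V(V−1))`. Mean pairwise distance is measured in the *background*
network by default — the question is how tightly the candidates cluster
inside the full network, and an induced-subgraph mode exists for the other
reading — averaging shortest-path lengths over connected unordered pairs
and counting disconnected pairs separately (mean is NaN when no pair
connects). Betweenness is unnormalized shortest-path betweenness on the
induced subnetwork (normalization optional); it is computed with networkx
and is cross-checked in the test suite against an independent brute-force
enumerator of all shortest paths on small graphs. The permutation null
draws uniform random node sets of equal size (a degree-matched option,
off by default, samples within log2-degree bins, with replacement inside a
bin) and reports the pseudocounted empirical p,
`(1 + #{null ≤ observed}) / (1 + n_perm)`.

## Synthetic fixtures

The generator emulates the layered structure of the real data: 120 mRNA,
60 miRNA, 50 lncRNA, 30 TF and 40 protein nodes wired by the six canonical
layers under their bipartite type constraints, background edge probability
`p_out = 0.01`, and a planted 20-node cross-layer module whose internal
layer-compatible pairs connect with `p_in = 0.5`; 10 seeds are drawn from
module nodes that carry at least one edge. These defaults give a sparse
(~260-edge) network in which the planted module is recoverable but not
trivial: cross-validated AUC ≈ 0.8 versus ≈ 0.45 for permuted seeds. All
sampling flows from one integer seed; no global RNG state is touched, and
written tables are byte-identical across same-seed runs. The drug-table
generator adds `n_drugs − 1` uniform decoy drugs and one planted drug
containing a chosen number of candidate genes.

What the fixture does *not* emulate: scale-free degree structure, the
orders-of-magnitude size of real interactomes (tens of thousands of nodes),
database noise and redundancy, or literature-biased seed curation. Passing
tests therefore demonstrate that the machinery is correct and that planted
signal of the stated strength is recovered — not that any particular AUC
will be attained on real disease data.

## Numerical and design choices

- Convergence: L1 tolerance 1e-10, cap 1000 iterations; at the default
  r = 0.4 convergence takes ~25 iterations on the fixture.
- Tie-breaks: all rankings and the sweep argmax are deterministic
  (lexicographic / smaller-r).
- Degenerate inputs: empty layers, zero-edge networks, unmappable seeds or
  gene sets, and out-of-bounds test parameters raise typed errors early;
  non-convergence and over-large k only warn.
- Problem sizes in the test suite and acceptance script (graphs of ≤ 300
  nodes, 30-replicate Monte-Carlo, 99 permutations) were chosen as the
  smallest sizes at which the Monte-Carlo bands in use (±0.05 on a null
  AUC, ±0.03 on sweep monotonicity) are comfortably stable.

## Known limitations

- Layers are unweighted; no scheme for interaction confidence scores.
- One connected walk: mass cannot reach components without seeds (their
  nodes rank at the bottom by design).
- The LOOCV null distribution is sensitive to tie structure on very sparse
  graphs, where many candidates share score 0 and lexicographic tie-breaks
  decide ranks.
- Identifier normalization handles case and whitespace, not cross-database
  synonym mapping; users supply consistently-identified tables.
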