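# Methods

This note records what `netclass` computes, how the synthetic data are
constructed, and the numerical choices behind both. Problem sizes quoted
here (800-node study network, 500-replicate nulls, 50 annealing restarts)
are this package's own desk-scale defaults, chosen to keep a full run in
minutes on one core while leaving every statistic well resolved.

## Model

The object of study is a simple directed graph over opaque string gene
identifiers (no self-loops, no duplicate edges, no symbol normalization)
together with named node classes — canonically drug targets (DTN),
somatically mutated genes (SMN) and GWAS genes (GGN) — that may overlap.
All distances are unweighted directed geodesics (BFS).

### Centrality

- Degrees are exact in/out counts.
- Out-closeness is reported raw, `C(v) = 1/Σ_x d(v,x)` over nodes reachable
  from `v` (0 for a node reaching nothing), and normalized as
  `(R_v/Σd)·(R_v/(n−1))` (Wasserman–Faust), which stays in [0, 1] on graphs
  that are not strongly connected and equals 1 on a complete digraph. The
  normalized variant is the default for class comparisons.
- Betweenness is Brandes' exact directed algorithm, endpoints excluded,
  unnormalized.
- Degree exponents come from ordinary least squares of `log(frequency)` on
  `log(degree)` over the distinct positive degrees — no binning, no cutoff
  selection. This estimator is simple and transparent but biased on sparse
  tails (long runs of frequency-1 degrees flatten the slope); the generator
  is truncated specifically so that the estimator is consistent with it
  (below).

### Control centrality

`C_c(v)` is the generic dimension of the controllable subspace for a single
input attached to `v`: the rank, for almost every weight assignment, of the
Krylov matrix `[b, Ab, A²b, …]` with `A[j,i]` the weight of edge `i→j` and
`b = e_v`. Generic rank is attained with probability 1 under random
weights, so the implementation draws independent integer weights in
`[1, 2^20)`, restricts `A` to the out-reachable subcomponent of `v` (the
Krylov vectors are supported there), computes the numeric rank by Arnoldi
orthonormalization with full reorthogonalization and a relative breakdown
tolerance of `1e-9`, and keeps the maximum over a small number of draws
(default 2–3). The test suite validates this against two independent
references: exact symbolic rank over the rational-function field (sympy)
and an exhaustive structural oracle (the largest "stem plus disjoint
cycles" cover of the reachable set, with cycle-coverability decided by
bipartite perfect matching) on all small graphs.

### Geodesic ratio and permutation null

For an ordered class pair `(first, second)` the overlap is removed from
both classes, then for each member `u` of a class the *nearest* geodesics
`E_out(u) = min_v d(u, v)` and `E_in(u) = min_v d(v, u)` toward/from the
other class are collected; absent values (no path) are dropped from means
with a logged count. `GR = mean(E_out)/mean(E_in)` and
`D = GR_first − GR_second`. `D > 0` means the first class is more
accessible *from* the second — the first class sits downstream. The
convention throughout the package (pipeline orderings, CLI, examples) is to
put the candidate downstream class first.

The null model rewires the observed graph by directed double edge swaps
(`(a→b, c→d) ⇒ (a→d, c→b)`), rejecting swaps that would create self-loops
or duplicates; `10·|E|` attempted swaps per replicate. Every node keeps its
exact in- and out-degree, so the null asks: is `D` explained by degree
alone? The one-sided empirical p-value over `N = 500` replicates is the
plain fraction `#{D_null ≥ D_obs}/N` (resolution `1/N`; an add-one smoothed
`(1+k)/(1+N)` is reported alongside). Replicate seeds derive from the
master seed by counter, so results are independent of generation order.
If the statistic is undefined (an all-absent nearest-geodesic vector) on
the observed network the test refuses to run; if undefined on more than 10%
of replicates the null is declared unusable.

### Hierarchy stratification and enrichment

Nodes are assigned to three layers (top/middle/bottom) by maximizing the
*hierarchy score* — the fraction of edges pointing strictly downward —
with simulated annealing (geometric cooling 1.5 → 0.02) restarted from ≥ 3
random labelings (default 50). Restarts are aligned by ascending mean
`(in-degree − out-degree)` per layer; a node's layer probability is the
fraction of restarts placing it there, and a hard label requires
probability > 0.5. This reproduces the output contract of
hierarchical-score maximization (three layers, per-node probabilities,
majority assignment) with a fully documented in-package objective; it is
not a reimplementation of any external tool.

Enrichment of a class in a layer (or in any annotation set) is the
two-sided Fisher exact test on the 2×2 membership table over the network
node set, with fold enrichment `(overlap/|class|)/(|target|/|universe|)`
and Benjamini–Hochberg adjustment across annotation sets within a class.
Layer enrichments (3 per class) are reported unadjusted.

## Synthetic data: what it emulates, and what it does not

The generator emulates three properties the analysis relies on:

1. **Heavy-tailed degrees.** Out-degrees are quantile-assigned from a
   truncated power law `p(k) ∝ k^(−γ)`, `k = 1..k_max` with
   `k_max = max(6, n^(1/γ))`, then multiplied by `degree_scale = 5` and
   shuffled. The truncation keeps the frequency-1 tail short enough that
   the raw log-log OLS estimator recovers γ (generator/fitter consistency,
   verified within ±0.4 at n = 2000 over 10 seeds); the constant scaling
   preserves the log-log slope exactly (`freq(s·k) ∝ (s·k)^(−γ)`) while
   densifying the network toward interactome-like mean degree (~8 at the
   defaults). Targets are chosen preferentially by in-degree (+1
   smoothing) with a 10% uniform admixture.
2. **Exact class structure.** Class sizes and pairwise/triple overlaps are
   allocated exactly by inclusion–exclusion over at most three classes.
3. **A tunable hierarchy.** Every node gets a latent depth in [0, 1]; class
   of rank r occupies the band [r/K, (r+1)/K) (first class shallowest).
   Each edge is reoriented — never added or removed — to point downhill
   with probability `hierarchy_bias`. For biases strictly between 0.5 and
   1, degree-preserving double edge swaps are then applied with Metropolis
   acceptance (`β = logit(bias)`) on a class-rank objective that rewards
   upstream-class → downstream-class member edges. This second stage plants
   placement correlation *beyond degree* — precisely the structure a
   degree-preserved null cannot reproduce, and therefore the signal the
   permutation test is meant to detect. At bias 0.5 orientation is a fair
   coin and the swaps are skipped, making equal-size classes exchangeable
   (the type-I regime); at bias 1.0 the swaps are skipped so the hard
   guarantee "every between-class edge points downhill (absent a reciprocal
   edge)" survives.

It does **not** emulate: biological edge semantics, curated pathway
modularity, literature-bias degree inflation of famous genes, or the exact
degree exponent of any real interactome *after* planting — reorientation
conserves each node's total degree but redistributes the in/out split, so
degree-exponent fits on a planted network with strong bias are shallower
than `gamma_target` (the generator-consistency guarantee applies to the
pre-planting graph, which is what the acceptance check fits).

## Statistical validation baked into the test suite

- **Calibration.** At bias 0.5 (exchangeable classes), across 200 synthetic
  datasets (n = 300, two 30-node classes) the test at α = 0.05 with 99
  rewirings per dataset rejects at a rate inside the exact binomial 99%
  interval around 0.05.
- **Power.** At bias 0.9 (n = 600, two 40-node classes, 200 rewirings), the
  test with the downstream class first rejects with `D > 0` in ≥ 90% of 20
  generator seeds (observed: 20/20 during development).
- **Oracles.** Geodesics vs Floyd–Warshall; betweenness vs geodesic-count
  combination and the closed form `B(i) = i·(L−i)` on directed paths;
  control centrality vs symbolic generic rank and the structural cactus
  oracle; Fisher p-values vs hypergeometric mass summation, exhaustive over
  all 2×2 tables with universe ≤ 32 plus 3000 sampled tables up to 60; BH
  vs the textbook step-up formula; 500 rewirings of a 1000-node network
  checked for exact degree preservation.

## Limitations

- The annealer is a heuristic; on large or weakly hierarchical graphs the
  best score is a lower bound and layer probabilities quantify restart
  instability, not posterior uncertainty.
- The OLS exponent estimator is adequate for the generator's truncated law
  but is not a substitute for maximum-likelihood tail fitting on real
  degree data.
- Control centrality is exact only generically; pathological weight
  coincidences are ruled out by multiple random draws, not by proof.
- The permutation test conditions on the degree sequence only; nulls
  preserving other features (e.g. reciprocity or clustering) would be
  stricter and are not implemented.
- Geodesic statistics treat all edges as equally reliable one-step
  relations; edge confidence scores are ignored.
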