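# Methods

## Model and notation

A weighted undirected network on `N ≥ 2` nodes is a symmetric association
matrix `W` with zero diagonal. Weights standardized to `[0, 1]` are read as
association strength; the *weighted cost* (connectivity strength) is the
mean of the `N(N−1)` off-diagonal entries. An unweighted graph's *cost* is
its edge count over the saturated count `M = N(N−1)/2`.

Thresholding is defined through ranks: the `M` upper-triangle weights are
ranked descending (rank 1 = strongest), percentile ranks are `rank/M`, and
`τ(W, k/M)` keeps exactly the `k` top-ranked edges. Consequences that the
implementation treats as contracts:

* the cost of `τ(W, c)` equals `c` **exactly** for every grid level `c`;
  off-grid costs are rejected rather than rounded;
* graphs along the grid are nested (each level adds one edge);
* `τ` — and hence any cost-integrated metric — is invariant under strictly
  monotone increasing elementwise transforms of `W`. For monotone
  *decreasing* transforms the rank order reverses; the ranking direction is
  an explicit flag (`descending=False` ranks weakest-first), which makes the
  decreasing case testable instead of silently redefining association.

Ties in the weights are resolved by lexicographic `(i, j)` index order,
never randomly: random allocation would inject spurious random topology at
the affected costs. `count_tied_ranks` reports the number of weights
involved in ties; the CLI warns when it is nonzero.

## Efficiency metrics

Global efficiency is the mean reciprocal shortest-path length over ordered
pairs, with `1/∞ = 0` for disconnected pairs (an explicit sentinel, so the
metric is defined at every sparsity). Local efficiency averages over nodes
the global efficiency of the neighbor-induced subgraph, each normalized by
its own ordered-pair count; subgraphs with fewer than two nodes (isolated
and degree-one nodes) score 0, which keeps local efficiency integrable over
the full cost range.

Unweighted all-pairs distances are computed by simultaneous BFS via iterated
boolean matrix products (pairs first reachable at the k-th adjacency power
are at hop distance k); this is exact, vectorizes well at the sizes the
grid sweep requires, and is cross-checked in the tests against networkx and
against exhaustive path enumeration on graphs of up to 7 nodes.

Weighted shortest paths run Dijkstra (scipy.sparse.csgraph) on edge lengths
`phi(w)`; `phi` is pluggable with the reciprocal `1/w` as default. Only maps
into `[1, ∞)` keep weighted efficiency in `[0, 1]`. Weights equal to zero
are rejected for weighted metrics (the network must be fully weighted);
rank-based operations have no such restriction. When every direct edge is
itself a weighted geodesic — guaranteed when `max W ≤ 2·min W`, since any
two-edge detour has length ≥ 2 ≥ 1/w — weighted efficiency equals weighted
cost to machine precision, which is the precise sense in which the weighted
metric adds little beyond connectivity strength.

## Distributions over cost

The cost grid excludes the null cost: every edge-based metric sits at its
floor there, so its inclusion would shift all networks' integrals equally
(the two-node example would score 1/2 instead of 1). A diagnostic
`uniform_integral_including_null` exposes exactly this effect.

The Beta-binomial pmf assigns the level with `k` edges the mass of
`BetaBinom(M−1, α, β)` at `x = k−1`; the shift restricts the support to the
M non-null levels. `α = β = 1` reproduces the uniform pmf exactly, and the
expected edge count obeys `1 + (M−1)·α/(α+β)`, which the tests verify to
1e−10. Evaluation goes through scipy's log-space pmf and one final
renormalization, since direct Beta-function ratios underflow at `M ≈ 4000`.
Asymmetric `(α, β)` are allowed.

Interval conditioning zeroes the pmf outside `[lower, upper]` and
renormalizes. On a discrete support the closure matters, so it is an
explicit argument (`closed` default, both half-open variants available).
Results integrated over a band are conditional on that band; the CLI echoes
the bounds and closure in every report row.

## Exact integration and Monte Carlo

`integrate_exact` walks the nested edge-insertion order once and evaluates
the metric only at levels with positive mass; `integrate_exact_many`
amortizes one walk across several pmfs (their supports' union), which is
how sensitivity analyses across distributions are computed. Identity with
the per-distribution path is unit-tested.

`mc_integrate` draws `n` costs i.i.d. from the pmf (seed mandatory,
recorded in the result), evaluates the metric once per distinct sampled
cost, and reports the mean, the MC standard error `sd(draws)/√n`, and the
running-mean trace; `confidence_band` forms `estimate ± m·SE` (default
`m = 2`). The estimator is the plain one — no stratification or antithetic
variates — because its SE is the quantity the convergence diagnostics are
built on. Requesting fewer than 2 samples is an error (the SE is
undefined).

## Synthetic generators

The generators stand in for real association matrices (the method's natural
inputs are correlation-derived brain networks, which ship with no public
fixture here):

* `random_weighted_network` — i.i.d. uniform(0, 1) off-diagonal weights;
  continuous draws make tied ranks a measure-zero event.
* `proportional_pair` — `W` and `a·W`: weighted costs in exact ratio `a`,
  identical threshold profiles.
* `two_node_pair` — the degenerate single-level grid.
* `layered_association_matrix` — weights strictly decreasing in a target
  rank order so the thresholded graph grows through prescribed bands:
  `regular` bands consume ring-lattice edges (ordered by ring distance,
  nearest neighbors first — the conventional lattice referent), `random`
  bands draw uniformly without replacement from unused pairs. Any strictly
  decreasing weight sequence realizes the same integrated topology (the
  monotone-invariance property used constructively), so weights are simply
  `(M−k+1)/(M+1)`. Default band boundaries split the grid into thirds; a
  regular/random/regular "hybrid" shares its first band with an all-regular
  matrix exactly, while its random middle layer makes it strictly more
  globally efficient over the full grid.

What the synthetic inputs do **not** emulate: the spatial autocorrelation,
measurement noise and inter-subject variability of real correlation
matrices, negative or zero associations, and differing numbers of positive
weights across networks. Passing tests therefore demonstrate the
mathematical contracts of the method, not robustness to those data
features; for sparse or tie-heavy real data the tied-rank diagnostic and
interval conditioning are the intended tools.

## Problem sizes and numerical choices

The verification suite runs at desk scale, chosen as the smallest sizes
that exercise each property fully: transforms and distributions at `N = 20`
(M = 190), weighted-cost equivalence at `N = 15`, the layered contrast and
MC calibration at the brain-parcellation scale `N = 90` (M = 4005, the
paper-scale grid), coverage over 100 seeds at 1000 samples per seed.
Equality assertions on transform invariance and thresholding are exact or
at 1e−12; pmf normalization at 1e−12; closed-form Beta-binomial mean at
1e−10. Symmetry validation tolerates relative asymmetry 1e−8 and averages
with the transpose; the diagonal is always forcibly zeroed. Grid membership
tolerates 1e−6 in units of edge count.

## Known limitations

* Cost-integration averages away cost-specific topological differences; two
  networks can differ in a band and agree on the full-grid integral (the
  layered example is constructed to show exactly this).
* Comparisons require equal node counts and, for meaningful rank
  comparisons, equal numbers of positive weights; for sparser networks the
  recommended route is interval conditioning over a band reflecting the
  common sparsity, which the tool exposes but does not auto-select.
* Dependence between the nested thresholded graphs is not modeled; the
  integral weights each level's topology marginally.
* Directed graphs and sign-aware analysis of negative associations are out
  of scope; standardization folds negative correlations into positive
  association (`|r|` default, `(r+1)/2` selectable — the two orderings
  differ on mixed-sign data, which is why the choice is explicit and
  echoed in outputs).
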