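# costnet

Cost-integrated topological analysis of weighted undirected networks.

## The problem

Brain connectivity studies (and weighted-network comparisons generally)
routinely threshold an association matrix — correlations between regional
fMRI time series, say — to obtain an unweighted graph whose topology can be
summarized by metrics such as global efficiency. But topology is inherently
confounded with *wiring cost*: a population with stronger mean association
produces denser graphs under any fixed cutoff, and denser graphs score
higher on essentially every integration metric. Comparing populations of
weighted networks therefore requires separating differences in connectivity
strength from differences in topology.

`costnet` implements the cost-integration approach to this problem, for
anyone comparing populations of weighted graphs of equal order: report

1. the **weighted cost** `K_W = mean of the off-diagonal standardized
   weights` (connectivity strength), and
2. **cost-integrated topological metrics**
   `E[T] = Σ_k P(C = c_k) · T(τ(W, c_k))`,
   where `τ(W, c)` thresholds the network to exactly the top `c·M` edges by
   percentile rank (`M = N(N−1)/2`), and the pmf `P` over the cost grid
   `{k/M : k = 1..M}` is uniform, Beta-binomial(α, β) on the shifted edge
   count, or either of these conditioned on a cost interval.

The key property — verified exhaustively by the test suite — is that the
integrated metric depends on the weights only through their ranks, so it is
invariant under every strictly monotone transform of the weight set: it
measures topology *controlling for* any monotone difference in connectivity
strength. By contrast the *weighted* efficiency (shortest paths on lengths
`1/w`) collapses to the weighted cost whenever every direct edge is a
weighted geodesic (guaranteed when `max W ≤ 2·min W`), so it mostly restates
connectivity strength.

Exact integration needs one metric evaluation per grid level; a seeded
Monte-Carlo estimator (`mean of T at n costs sampled from the pmf`, with its
standard error `sd/√n` and running-mean trace) approximates it at a fraction
of the computation.

## Worked example

```python
import numpy as np
import costnet as cn

base = cn.random_weighted_network(20, seed=31)     # N=20, M=190 cost levels
net1, net2 = cn.proportional_pair(base, 0.5)       # W and 0.5*W

print(cn.weighted_cost(net1), cn.weighted_cost(net2))
# 0.5226257255333734 0.2613128627666867             <- costs differ 2:1

grid = cn.make_cost_grid(20)
uni = cn.uniform_distribution(grid)
print(cn.integrate_exact(net1, cn.global_efficiency, uni),
      cn.integrate_exact(net2, cn.global_efficiency, uni))
# 0.6916708547685002 0.6916708547685002             <- topology identical

est = cn.mc_integrate(net1, cn.global_efficiency, uni, n=500, seed=7)
print(est.estimate, est.standard_error)
# 0.7005870300751874 0.01085331232942124            <- MC agrees within 2 SE
```

The two networks differ only in connectivity strength; thresholding either
at any grid cost selects the same edges, so their cost-integrated global
efficiencies are *exactly* equal while their weighted costs sit in the exact
ratio 0.5. The MC estimate reproduces the exact integral within its
reported ±2 SE band.

The same analyses run from the shell on dense-matrix or edge-list files:

```sh
costnet cost subject1.csv subject2.csv --standardize absolute
costnet integrate subject1.csv --dist betabinom --alpha 3 --beta 3
costnet mc subject1.csv --n-samples 1000 --seed 1 --out trace.tsv
costnet simulate --kind layered --n-nodes 90 --out-dir fixtures/
```

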