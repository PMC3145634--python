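"""Monte-Carlo approximation of cost-integrated metrics.

The exact integral needs one metric evaluation per grid level (M of them,
4005 for a 90-node network).  Re-expressing it as the expectation of the
metric under the cost pmf allows a plain MC estimate: draw n costs i.i.d.
from the pmf, evaluate the metric at each, and average.  The estimate
converges to the exact integral almost surely; the MC standard error
(sample standard deviation over sqrt(n)) quantifies its accuracy, and the
running mean with a +/- 2 SE band makes convergence visible.

Sampling is with replacement from the pmf — the plain estimator, no variance
reduction — and the seed is a mandatory argument recorded in the result.
Within one call the metric is evaluated once per *distinct* sampled cost
(the thresholded graph at a grid cost is deterministic), which changes no
estimate but avoids redundant shortest-path computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distributions import CostDistribution, sample_costs
from .integration import MetricFunction, metric_profile
from .network import NetworkError, WeightedNetwork

__all__ = ["MCEstimate", "mc_integrate", "confidence_band", "running_trace"]


@dataclass(frozen=True)
class MCEstimate:
    """Result of a Monte-Carlo cost-integration."""

    estimate: float
    standard_error: float
    n_samples: int
    running_mean: np.ndarray
    seed: int
    values: np.ndarray
    """The n metric draws, in sampling order."""


def mc_integrate(
    net: WeightedNetwork,
    metric: MetricFunction,
    dist: CostDistribution,
    n: int,
    seed: int,
) -> MCEstimate:
    """Plain MC estimate of the cost-integrated metric with its SE."""
    if n < 2:
        raise NetworkError("MC standard error needs at least 2 samples")
    if dist.grid.n_nodes != net.n_nodes:
        raise NetworkError("distribution grid does not match the network size")
    draws = sample_costs(dist, n, seed)
    ks = np.rint(draws * dist.grid.m).astype(int)
    uniq, inverse = np.unique(ks, return_inverse=True)
    uniq_values = metric_profile(net, metric, uniq)
    values = uniq_values[inverse]
    running = np.cumsum(values) / np.arange(1, n + 1)
    se = float(values.std(ddof=1) / math.sqrt(n))
    return MCEstimate(
        estimate=float(running[-1]),
        standard_error=se,
        n_samples=n,
        running_mean=running,
        seed=seed,
        values=values,
    )


def confidence_band(
    est: MCEstimate, multiplier: float = 2.0
) -> tuple[float, float]:
    """Asymptotic band ``estimate +/- multiplier * SE`` (default 2 SE)."""
    if multiplier <= 0:
        raise NetworkError("band multiplier must be positive")
    half = multiplier * est.standard_error
    return est.estimate - half, est.estimate + half


def running_trace(est: MCEstimate) -> list[tuple[int, float, float]]:
    """Per-sample (index, running mean, running SE) for convergence plots.

    The SE at the first sample is undefined and reported as NaN; the last row
    reproduces the final estimate and standard error.
    """
    n = est.n_samples
    idx = np.arange(1, n + 1)
    sq = np.cumsum(est.values**2)
    mean = est.running_mean
    with np.errstate(invalid="ignore"):
        var = (sq - idx * mean**2) / (idx - 1)
    var = np.clip(var, 0.0, None)
    se = np.sqrt(var / idx)
    se[0] = np.nan
    return list(zip(idx.tolist(), mean.tolist(), se.tolist()))
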