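"""Probability mass functions over the cost grid.

Cost-integration treats the cost of the thresholded graph as a discrete
random variable on the grid ``{k/M}``.  Three families are provided:

* uniform — every achievable cost equally likely;
* Beta-binomial(alpha, beta) — the level with ``k`` edges receives the
  Beta-binomial mass at ``x = k - 1`` with trial count ``M - 1`` (the shift
  accounts for the excluded null cost); ``alpha = beta = 1`` recovers the
  uniform exactly, and larger symmetric parameters de-emphasize the extreme
  sparse/dense regimes;
* interval-conditioned — any pmf restricted to a sub-range of the grid and
  renormalized, making integration over a cost band an explicit, reportable
  conditioning choice.  Because the grid is discrete, whether the interval
  endpoints are included changes the conditional pmf, so the closure is an
  explicit argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
from scipy.stats import betabinom

from .network import CostGrid, NetworkError

__all__ = [
    "CostDistribution",
    "uniform_distribution",
    "beta_binomial_distribution",
    "restrict_to_interval",
    "sample_costs",
]

_CLOSURES = ("closed", "left_half_open", "right_half_open")


@dataclass(frozen=True)
class CostDistribution:
    """A pmf aligned to the levels of a :class:`CostGrid`."""

    grid: CostGrid
    pmf: np.ndarray
    descriptor: Mapping[str, Any]

    def __post_init__(self) -> None:
        p = np.asarray(self.pmf, dtype=float)
        if p.shape != (self.grid.m,):
            raise NetworkError("pmf length must match the grid")
        if (p < 0).any():
            raise NetworkError("pmf entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise NetworkError("pmf must sum to 1")
        p = p.copy()
        p.flags.writeable = False
        object.__setattr__(self, "pmf", p)
        object.__setattr__(self, "descriptor", dict(self.descriptor))

    def mean_edges(self) -> float:
        """Expected edge count E[K] = sum_k k * pmf(k/M)."""
        return float(np.arange(1, self.grid.m + 1) @ self.pmf)


def uniform_distribution(grid: CostGrid) -> CostDistribution:
    """Equal mass 1/M on every grid level."""
    p = np.full(grid.m, 1.0 / grid.m)
    return CostDistribution(grid=grid, pmf=p, descriptor={"family": "uniform"})


def beta_binomial_distribution(
    grid: CostGrid, alpha: float, beta: float
) -> CostDistribution:
    """Beta-binomial mass over edge counts, shifted onto the non-null grid.

    The level with k edges (k = 1..M) gets ``BetaBinom(M - 1, alpha, beta)``
    mass at ``x = k - 1``.  Evaluated through scipy's log-space pmf and
    renormalized once to absorb rounding (M can reach thousands).
    """
    if alpha <= 0 or beta <= 0:
        raise NetworkError("Beta-binomial parameters must be positive")
    m = grid.m
    p = betabinom.pmf(np.arange(m), m - 1, alpha, beta)
    p = p / p.sum()
    return CostDistribution(
        grid=grid,
        pmf=p,
        descriptor={"family": "betabinom", "alpha": float(alpha), "beta": float(beta)},
    )


def restrict_to_interval(
    dist: CostDistribution,
    lower: float,
    upper: float,
    closure: str = "closed",
) -> CostDistribution:
    """Condition a pmf on a cost interval and renormalize.

    ``closure`` selects which endpoints belong to the support: ``closed``
    keeps both, ``left_half_open`` drops ``lower``, ``right_half_open`` drops
    ``upper``.
    """
    if closure not in _CLOSURES:
        raise NetworkError(f"closure must be one of {_CLOSURES}")
    grid = dist.grid
    k_lo = grid.index_of(lower)
    k_hi = grid.index_of(upper)
    if k_lo > k_hi:
        raise NetworkError("lower bound must not exceed upper bound")
    if closure == "left_half_open":
        k_lo += 1
    elif closure == "right_half_open":
        k_hi -= 1
    if k_lo > k_hi:
        raise NetworkError("interval closure leaves an empty support")
    mask = np.zeros(grid.m, dtype=bool)
    mask[k_lo - 1 : k_hi] = True
    p = np.where(mask, dist.pmf, 0.0)
    total = p.sum()
    if total <= 0.0:
        raise NetworkError("restricted pmf has zero mass on the interval")
    desc = dict(dist.descriptor)
    desc.update(
        interval=(float(lower), float(upper)),
        closure=closure,
    )
    return CostDistribution(grid=grid, pmf=p / total, descriptor=desc)


def sample_costs(dist: CostDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. grid levels from the pmf (reproducible by seed)."""
    if n < 1:
        raise NetworkError("need at least one sample")
    rng = np.random.default_rng(seed)
    idx = rng.choice(dist.grid.m, size=n, p=dist.pmf)
    return dist.grid.levels[idx]
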