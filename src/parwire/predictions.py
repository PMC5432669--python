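"""Closed-form and Monte-Carlo predictors for connector sizes, allocation
counts, and per-VP source occupancy.

For a balanced random network of N neurons (fraction epsilon excitatory)
with fixed in-degree K distributed over VP virtual processes:

* expected connector sizes per source group:
  ``k_EE = eps*K/VP``, ``k_EI = (1-eps)*K/VP``, ``k_I = K/VP``;
* dense regime (k >= K_cutoff), per S sources of mean connector size k:
  ``n_alloc = (4 + ceil(log2(k/K_cutoff))) * S``,
  ``n_free  = (3 + ceil(log2(k/K_cutoff))) * S``;
* sparse regime (almost all sources have <= 1 local connection):
  ``n_alloc = 2 * N1c``, ``n_free = N1c``;
* per-VP occupancy classes from the Poisson limit of scattering
  ``K_VP = floor(N*K/VP)`` incoming connections over N sources with
  lambda = K_VP/N:
  ``N0c = N*exp(-lambda)``, ``N1c = N*lambda*exp(-lambda)``,
  ``N>1c = N - N0c - N1c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Tuple

import numpy as np


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (display convention for connector sizes)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class NetworkSpec:
    """Balanced random network parameters."""

    N: int
    K: int
    epsilon: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie strictly between 0 and 1")
        if self.N < 1 or self.K < 0:
            raise ValueError("N must be positive and K non-negative")

    @property
    def n_E(self) -> float:
        return self.epsilon * self.K

    @property
    def n_I(self) -> float:
        return (1.0 - self.epsilon) * self.K

    @property
    def N_E(self) -> float:
        return self.epsilon * self.N

    @property
    def N_I(self) -> float:
        return (1.0 - self.epsilon) * self.N


@dataclass(frozen=True)
class ConnectorSizePrediction:
    k_EE: float
    k_EI: float
    k_I: float

    def rounded(self, decimals: int = 1) -> "ConnectorSizePrediction":
        return ConnectorSizePrediction(
            round_half_up(self.k_EE, decimals),
            round_half_up(self.k_EI, decimals),
            round_half_up(self.k_I, decimals),
        )


@dataclass(frozen=True)
class AllocationPrediction:
    n_alloc: int
    n_free: int


@dataclass(frozen=True)
class OccupancyPrediction:
    N_VP: int
    K_VP: int
    N_0c: float
    N_1c: float
    N_gt1c: float


def expected_connector_sizes(spec: NetworkSpec, VP: int) -> ConnectorSizePrediction:
    """Mean per-VP connector sizes by source group."""
    if VP < 1:
        raise ValueError("VP must be >= 1")
    return ConnectorSizePrediction(
        k_EE=spec.epsilon * spec.K / VP,
        k_EI=(1.0 - spec.epsilon) * spec.K / VP,
        k_I=spec.K / VP,
    )


def _doublings(k: float, K_cutoff: int) -> int:
    return max(0, math.ceil(math.log2(k / K_cutoff)))


def predicted_memory_ops_dense(S: int, k: float, K_cutoff: int = 3) -> AllocationPrediction:
    """Modeled alloc/free counts for S sources of mean connector size k in
    the dense (dynamically-sized container) regime."""
    if k < K_cutoff:
        raise ValueError(
            f"mean connector size {k} below K_cutoff={K_cutoff}: fixed-size regime, "
            "use single_source_ledger / predicted_memory_ops_sparse"
        )
    d = _doublings(k, K_cutoff)
    return AllocationPrediction(n_alloc=(4 + d) * S, n_free=(3 + d) * S)


def predicted_memory_ops_sparse(N1c: int) -> AllocationPrediction:
    """Modeled alloc/free counts when sources have at most one local
    connection each."""
    return AllocationPrediction(n_alloc=2 * N1c, n_free=N1c)


def single_source_ledger(k: int, K_cutoff: int = 3) -> Tuple[int, int]:
    """Exact (alloc, free) for one source accumulating k same-type local
    connections, by replay of the connector state machine."""
    if k < 1:
        return (0, 0)
    if k < K_cutoff:
        # registration (1a+1f) + initial connector (1a) + k-1 replacements
        return (2 + (k - 1), 1 + (k - 1))
    d = _doublings(k, K_cutoff)
    return (4 + d, 3 + d)


def benchmark_memory_ops(
    spec: NetworkSpec, VP: int, K_cutoff: int = 3
) -> AllocationPrediction:
    """Per-VP alloc/free prediction for the balanced benchmark: dense-regime
    counts summed over the EE, EI and I source groups."""
    sizes = expected_connector_sizes(spec, VP)
    S_E = int(round(spec.N_E))
    S_I = int(round(spec.N_I))
    total_alloc = 0
    total_free = 0
    for S, k in ((S_E, sizes.k_EE), (S_E, sizes.k_EI), (S_I, sizes.k_I)):
        p = predicted_memory_ops_dense(S, k, K_cutoff)
        total_alloc += p.n_alloc
        total_free += p.n_free
    return AllocationPrediction(total_alloc, total_free)


def occupancy_expectation(spec: NetworkSpec, VP: int) -> OccupancyPrediction:
    """Expected per-VP neuron/synapse counts and source-occupancy classes."""
    if VP < 1:
        raise ValueError("VP must be >= 1")
    N, K = spec.N, spec.K
    N_VP = round(N / VP)
    K_VP = (N * K) // VP
    lam = K_VP / N
    n0 = N * math.exp(-lam)
    n1 = N * lam * math.exp(-lam)
    return OccupancyPrediction(
        N_VP=N_VP, K_VP=K_VP, N_0c=n0, N_1c=n1, N_gt1c=N - n0 - n1
    )


@dataclass(frozen=True)
class OccupancyEstimate:
    mean: Tuple[float, float, float]
    stderr: Tuple[float, float, float]
    replicates: int
    draws_per_replicate: int


def occupancy_montecarlo(
    spec: NetworkSpec,
    VP: int,
    replicates: int = 100,
    seed: int = 12345,
    draws: Optional[int] = None,
) -> OccupancyEstimate:
    """Stochastic oracle for :func:`occupancy_expectation`.

    Simulates one VP's incoming-connection draws (``K_VP`` uniform source
    picks over N sources by default) and tallies sources hit 0, 1 or more
    than once.  Returns per-class means and standard errors over replicates.
    """
    N = spec.N
    if draws is None:
        draws = (spec.N * spec.K) // VP
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, 0))))
    tallies = np.empty((replicates, 3), dtype=float)
    for r in range(replicates):
        picks = rng.integers(0, N, size=draws)
        _, counts = np.unique(picks, return_counts=True)
        n1 = int(np.count_nonzero(counts == 1))
        n_more = len(counts) - n1
        tallies[r] = (N - len(counts), n1, n_more)
    mean = tallies.mean(axis=0)
    if replicates > 1:
        stderr = tallies.std(axis=0, ddof=1) / math.sqrt(replicates)
    else:
        stderr = np.zeros(3)
    return OccupancyEstimate(
        mean=tuple(mean), stderr=tuple(stderr),
        replicates=replicates, draws_per_replicate=draws,
    )
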