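"""Exact ideal observer for the breadth-depth sampling task.

Allocating ``n_i`` samples to supplier i and observing ``k_i`` successes
yields the posterior-mean value ``(k_i + alpha) / (n_i + alpha + beta)``
under the Beta(alpha, beta) prior.  Because ``k_i`` follows a
Beta-Binomial(n_i; alpha, beta) distribution, the expected reward of a
whole sample *partition* (n_1, ..., n_m) is the expected maximum of m
independent discrete posterior-mean distributions, which we evaluate
exactly by multiplying CDFs over the union of support values:
``P(max <= v) = prod_i F_i(v)``.

The optimal policy per capacity is found by exhaustive search over all
integer partitions of the capacity (8349 partitions at capacity 32), a
deterministic replacement for Monte-Carlo estimation; a Monte-Carlo
estimator is retained as an independent cross-check.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, List, Sequence, Set, Tuple

import numpy as np
from scipy.stats import betabinom

from .task import Environment, TrialRecord

__all__ = [
    "ValueDistribution",
    "OptimalPolicyEntry",
    "beta_binomial_pmf",
    "posterior_mean",
    "value_distribution",
    "expected_max_value",
    "enumerate_partitions",
    "count_partitions",
    "optimal_allocation",
    "optimal_curve",
    "monte_carlo_expected_value",
    "normative_choice",
    "proportional_choice",
]

#: expected values closer than this are treated as tied
TIE_TOL = 1e-12


@dataclass(frozen=True)
class ValueDistribution:
    """Distribution of the posterior-mean value after n samples.

    ``support[k] = (k + alpha) / (n + alpha + beta)`` with Beta-Binomial
    probabilities; strictly increasing support, probabilities sum to one.
    """

    support: Tuple[float, ...]
    probs: Tuple[float, ...]


@dataclass(frozen=True)
class OptimalPolicyEntry:
    """The reward-maximizing sample partition at one capacity."""

    capacity: int
    best_partition: Tuple[int, ...]
    m_opt: int
    expected_value: float

    @property
    def expected_reward(self) -> float:
        return 100.0 * self.expected_value


def beta_binomial_pmf(k: int, n: int, env: Environment) -> float:
    """P(k successes in n samples) when the success rate is Beta(alpha, beta)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    return float(betabinom.pmf(k, n, env.alpha, env.beta))


def posterior_mean(k: int, n: int, env: Environment) -> float:
    """Posterior-mean success probability after k successes in n samples."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    return (k + env.alpha) / (n + env.alpha + env.beta)


@lru_cache(maxsize=None)
def _value_arrays(n: int, alpha: float, beta: float) -> Tuple[np.ndarray, np.ndarray]:
    k = np.arange(n + 1)
    probs = betabinom.pmf(k, n, alpha, beta)
    support = (k + alpha) / (n + alpha + beta)
    return support, np.cumsum(probs)


def value_distribution(n: int, env: Environment) -> ValueDistribution:
    """Posterior-mean value distribution after n samples on one supplier."""
    support, cdf = _value_arrays(n, env.alpha, env.beta)
    probs = np.diff(np.concatenate(([0.0], cdf)))
    return ValueDistribution(tuple(support), tuple(probs))


def expected_max_value(partition: Sequence[int], env: Environment) -> float:
    """Exact expected maximum posterior mean over the parts of a partition.

    Each part n_i contributes an independent Beta-Binomial posterior-mean
    distribution; the expectation of their maximum is computed from the
    product of CDFs on the merged (1e-12-rounded) support grid.
    """
    parts = tuple(int(n) for n in partition)
    if len(parts) == 0:
        raise ValueError("partition must be non-empty")
    if any(n < 1 for n in parts):
        raise ValueError("partition parts must be positive")
    return _expected_max_cached(tuple(sorted(parts, reverse=True)), env.alpha, env.beta)


@lru_cache(maxsize=200_000)
def _expected_max_cached(parts: Tuple[int, ...], alpha: float, beta: float) -> float:
    supports = []
    cdfs = []
    for n in parts:
        s, c = _value_arrays(n, alpha, beta)
        supports.append(np.round(s, 12))
        cdfs.append(c)
    grid = np.unique(np.concatenate(supports))
    g = np.ones_like(grid)
    for s, c in zip(supports, cdfs):
        idx = np.searchsorted(s, grid, side="right") - 1
        fi = np.where(idx >= 0, c[np.clip(idx, 0, len(c) - 1)], 0.0)
        g *= fi
    pmax = np.diff(np.concatenate(([0.0], g)))
    return float(np.dot(grid, pmax))


def enumerate_partitions(capacity: int, max_parts: int) -> Iterator[Tuple[int, ...]]:
    """All integer partitions of ``capacity`` with at most ``max_parts`` parts.

    Canonical order: parts non-increasing within a partition; partitions
    emitted in decreasing lexicographic order, e.g. for capacity 4:
    (4), (3,1), (2,2), (2,1,1), (1,1,1,1).
    """
    if capacity < 1 or max_parts < 1:
        raise ValueError("capacity and max_parts must be >= 1")

    def _gen(remaining: int, largest: int, prefix: List[int]) -> Iterator[Tuple[int, ...]]:
        if remaining == 0:
            yield tuple(prefix)
            return
        if len(prefix) == max_parts:
            return
        # a feasibility bound: the remaining slots must be able to absorb the rest
        slots = max_parts - len(prefix)
        for p in range(min(remaining, largest), 0, -1):
            if p * slots < remaining:
                break
            prefix.append(p)
            yield from _gen(remaining - p, p, prefix)
            prefix.pop()

    return _gen(capacity, capacity, [])


def count_partitions(capacity: int, max_parts: int) -> int:
    """Number of partitions of ``capacity`` into at most ``max_parts`` parts."""
    return sum(1 for _ in enumerate_partitions(capacity, max_parts))


def _tie_break_key(partition: Tuple[int, ...]) -> Tuple[int, Tuple[int, ...]]:
    # prefer fewer parts, then the lexicographically largest non-increasing
    # partition (i.e. the deepest allocation among tied candidates)
    return (len(partition), tuple(-p for p in partition))


@lru_cache(maxsize=None)
def _optimal_allocation_cached(
    capacity: int, alpha: float, beta: float, max_parts: int
) -> Tuple[Tuple[int, ...], float]:
    best_partition: Tuple[int, ...] | None = None
    best_value = -np.inf
    for part in enumerate_partitions(capacity, max_parts):
        v = _expected_max_cached(part, alpha, beta)
        if v > best_value + TIE_TOL:
            best_partition, best_value = part, v
        elif abs(v - best_value) <= TIE_TOL and best_partition is not None:
            if _tie_break_key(part) < _tie_break_key(best_partition):
                best_partition = part
                best_value = max(best_value, v)
    assert best_partition is not None
    return best_partition, best_value


def optimal_allocation(
    capacity: int, env: Environment, max_parts: int
) -> OptimalPolicyEntry:
    """Exhaustive-search optimal partition of ``capacity`` samples.

    ``max_parts`` is the number of available suppliers.  Ties within 1e-12
    are broken toward fewer parts, then toward the deeper partition.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    part, value = _optimal_allocation_cached(capacity, env.alpha, env.beta, max_parts)
    return OptimalPolicyEntry(capacity, part, len(part), value)


def optimal_curve(
    env: Environment, capacities: Sequence[int], max_parts: int
) -> List[OptimalPolicyEntry]:
    """Optimal policy for each capacity (the breadth-depth trade-off curve)."""
    return [optimal_allocation(int(c), env, max_parts) for c in capacities]


def monte_carlo_expected_value(
    partition: Sequence[int],
    env: Environment,
    n_sims: int,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of ``expected_max_value``.

    Kept as an independent oracle for the exact CDF-product computation.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    parts = np.asarray(partition, dtype=int)
    p = rng.beta(env.alpha, env.beta, size=(n_sims, len(parts)))
    k = rng.binomial(parts, p)
    values = (k + env.alpha) / (parts + env.alpha + env.beta)
    best = values.max(axis=1)
    return float(best.mean()), float(best.std(ddof=1) / math.sqrt(n_sims))


def _argmax_set(scores: "dict[int, float]") -> Set[int]:
    top = max(scores.values())
    return {i for i, v in scores.items() if v >= top - TIE_TOL}


def normative_choice(trial: TrialRecord, env: Environment) -> Set[int]:
    """Sampled suppliers maximizing the posterior-mean value V_norm.

    ``V_norm_i = (sum of outcomes on i + alpha) / (n_i + alpha + beta)``;
    returns the argmax set (more than one supplier on exact ties).
    """
    tally = trial.successes_by_supplier()
    scores = {i: posterior_mean(k, n, env) for i, (k, n) in tally.items()}
    return _argmax_set(scores)


def proportional_choice(trial: TrialRecord) -> Set[int]:
    """Sampled suppliers maximizing the prior-free proportion V_prop = k_i / n_i."""
    tally = trial.successes_by_supplier()
    scores = {i: k / n for i, (k, n) in tally.items()}
    return _argmax_set(scores)
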