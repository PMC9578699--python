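"""Domain types and the generative model of the breadth-depth sampling task.

The task: on each trial an agent receives a budget of ``capacity`` samples
(coins) and spends them one by one on any of ``n_suppliers`` alternatives.
Each supplier i carries an unknown success probability ``p_i``, drawn
independently per trial from a Beta(alpha, beta) prior describing the
richness of the environment.  Every sample placed on supplier i returns a
Bernoulli(p_i) outcome.  After all samples are spent the agent buys 100
units from exactly one *sampled* supplier; the reward is the number of
successes, Binomial(100, p_chosen).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Environment",
    "DesignSpec",
    "SampleAllocation",
    "TrialRecord",
    "CANONICAL_ENVIRONMENTS",
    "DESIGNS",
    "draw_supplier_qualities",
    "simulate_trial",
]

#: canonical (alpha, beta) shapes; prior means 0.25 / 0.50 / 0.75
CANONICAL_ENVIRONMENTS: Mapping[str, Tuple[float, float]] = {
    "poor": (1.0 / 3.0, 1.0),
    "neutral": (3.0, 3.0),
    "rich": (1.0, 1.0 / 3.0),
}

PURCHASE_SIZE = 100


class InvalidEnvironmentError(ValueError):
    """Raised for non-positive Beta shape parameters."""


class ContractViolationError(ValueError):
    """Raised when a trial violates a task-rule invariant."""


@dataclass(frozen=True)
class Environment:
    """A supplier-quality prior: qualities p_i ~ Beta(alpha, beta).

    Parameters
    ----------
    label:
        One of ``poor``, ``neutral``, ``rich`` or ``custom``.
    alpha, beta:
        Positive Beta shape parameters.  The prior mean
        ``alpha / (alpha + beta)`` is the environment's richness.
    """

    label: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise InvalidEnvironmentError(
                f"Beta shapes must be positive, got ({self.alpha}, {self.beta})"
            )

    @classmethod
    def from_label(cls, label: str) -> "Environment":
        try:
            a, b = CANONICAL_ENVIRONMENTS[label]
        except KeyError:
            raise InvalidEnvironmentError(
                f"unknown environment label {label!r}; use one of "
                f"{sorted(CANONICAL_ENVIRONMENTS)} or construct a custom Environment"
            ) from None
        return cls(label, a, b)

    @property
    def prior_mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def prior_variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


def poor() -> Environment:
    return Environment.from_label("poor")


def neutral() -> Environment:
    return Environment.from_label("neutral")


def rich() -> Environment:
    return Environment.from_label("rich")


@dataclass(frozen=True)
class DesignSpec:
    """An experimental design: which capacities, how many suppliers, how often.

    ``env_schedule`` lists the environment labels presented in blocks:
    length three for within-subject designs, length one for between-subject
    designs (where each participant sees a single environment).
    """

    name: str
    capacity_set: Tuple[int, ...]
    n_suppliers: int
    reps_per_capacity_per_env: int = 8
    env_schedule: Tuple[str, ...] = ("poor", "neutral", "rich")

    def __post_init__(self) -> None:
        caps = tuple(sorted(self.capacity_set))
        object.__setattr__(self, "capacity_set", caps)
        if any(c < 2 for c in caps):
            raise ValueError("capacities must be >= 2")
        if max(caps) > self.n_suppliers:
            raise ValueError("max capacity cannot exceed the number of suppliers")

    @property
    def n_trials_per_participant(self) -> int:
        return (
            len(self.capacity_set)
            * self.reps_per_capacity_per_env
            * len(self.env_schedule)
        )

    def with_environments(self, envs: Sequence[str]) -> "DesignSpec":
        return replace(self, env_schedule=tuple(envs))


#: the four canonical designs (216 / 72 / 120 / 40 trials per participant)
DESIGNS: Mapping[str, DesignSpec] = {
    "W10": DesignSpec("W10", tuple(range(2, 11)), 10),
    "B10": DesignSpec("B10", tuple(range(2, 11)), 10, env_schedule=("neutral",)),
    "W32": DesignSpec("W32", (2, 4, 8, 16, 32), 32),
    "B32": DesignSpec("B32", (2, 4, 8, 16, 32), 32, env_schedule=("neutral",)),
}


@dataclass(frozen=True)
class SampleAllocation:
    """An ordered allocation of ``capacity`` samples to suppliers.

    ``sequence`` holds 0-based supplier indices in allocation order; the
    multiset of per-supplier counts and the number of distinct suppliers
    sampled (M) are derived.
    """

    sequence: Tuple[int, ...]
    n_suppliers: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", tuple(int(i) for i in self.sequence))
        if len(self.sequence) == 0:
            raise ContractViolationError("allocation sequence is empty")
        if any(i < 0 or i >= self.n_suppliers for i in self.sequence):
            raise ContractViolationError(
                f"supplier indices must lie in [0, {self.n_suppliers})"
            )

    @property
    def capacity(self) -> int:
        return len(self.sequence)

    @property
    def counts(self) -> Counter:
        """Samples per sampled supplier (supplier index -> count)."""
        return Counter(self.sequence)

    @property
    def partition(self) -> Tuple[int, ...]:
        """Per-supplier counts as a non-increasing integer partition."""
        return tuple(sorted(self.counts.values(), reverse=True))

    @property
    def m(self) -> int:
        """Number of distinct suppliers sampled."""
        return len(set(self.sequence))


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial of the task."""

    participant_id: str
    design: str
    environment: str
    block_index: int
    trial_index: int
    capacity: int
    allocation: SampleAllocation
    outcomes: Tuple[int, ...]
    chosen_supplier: int
    reward: int
    truth_p: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(int(o) for o in self.outcomes))
        if self.allocation.capacity != self.capacity:
            raise ContractViolationError(
                f"allocation length {self.allocation.capacity} != capacity {self.capacity}"
            )
        if len(self.outcomes) != self.capacity:
            raise ContractViolationError("one outcome per allocated sample required")
        if any(o not in (0, 1) for o in self.outcomes):
            raise ContractViolationError("outcomes must be 0/1")
        if self.chosen_supplier not in self.allocation.counts:
            raise ContractViolationError(
                "chosen supplier must be among the sampled suppliers"
            )
        if not (0 <= self.reward <= PURCHASE_SIZE):
            raise ContractViolationError(f"reward must lie in [0, {PURCHASE_SIZE}]")
        if self.truth_p is not None:
            object.__setattr__(
                self, "truth_p", tuple(float(p) for p in self.truth_p)
            )

    def successes_by_supplier(self) -> "dict[int, Tuple[int, int]]":
        """Map sampled supplier -> (k_i successes, n_i samples)."""
        tally: "dict[int, list]" = {}
        for idx, out in zip(self.allocation.sequence, self.outcomes):
            k, n = tally.get(idx, (0, 0))
            tally[idx] = (k + out, n + 1)
        return tally


ChoiceRule = Callable[[Sequence[int], SampleAllocation], int]


def draw_supplier_qualities(
    env: Environment, n_suppliers: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. supplier success probabilities from the environment prior."""
    if n_suppliers < 1:
        raise ValueError("n_suppliers must be >= 1")
    return rng.beta(env.alpha, env.beta, size=n_suppliers)


def simulate_trial(
    env: Environment,
    capacity: int,
    allocation: SampleAllocation,
    choice_rule: ChoiceRule,
    rng: np.random.Generator,
    *,
    truth_p: Optional[Sequence[float]] = None,
    participant_id: str = "sim",
    design: str = "custom",
    block_index: int = 0,
    trial_index: int = 0,
) -> TrialRecord:
    """Run one trial of the generative model.

    Qualities are drawn fresh from the prior unless ``truth_p`` pins them.
    Per-sample outcomes are Bernoulli(p_i) for the supplier receiving the
    sample; the final reward is Binomial(100, p_chosen).
    """
    if allocation.capacity != capacity:
        raise ContractViolationError("allocation does not match capacity")
    if truth_p is None:
        p = draw_supplier_qualities(env, allocation.n_suppliers, rng)
    else:
        p = np.asarray(truth_p, dtype=float)
        if p.shape != (allocation.n_suppliers,):
            raise ValueError("truth_p must list one probability per supplier")
    outcomes = tuple(
        int(rng.random() < p[i]) for i in allocation.sequence
    )
    chosen = int(choice_rule(outcomes, allocation))
    if chosen not in allocation.counts:
        raise ContractViolationError(
            f"choice rule selected unsampled supplier {chosen}"
        )
    reward = int(rng.binomial(PURCHASE_SIZE, p[chosen]))
    return TrialRecord(
        participant_id=participant_id,
        design=design,
        environment=env.label,
        block_index=block_index,
        trial_index=trial_index,
        capacity=capacity,
        allocation=allocation,
        outcomes=outcomes,
        chosen_supplier=chosen,
        reward=reward,
        truth_p=tuple(float(x) for x in p),
    )
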