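"""Synthetic behavioural agents for the breadth-depth task.

Generates trial-level datasets with the statistical structure the
analyses assume: a power-law number of sampled alternatives M ~ C^w
corrupted by binomial or Gaussian noise, a configurable split of samples
across the selected alternatives, a configurable allocation order, final
choices by the normative or proportional rule (with an optional lapse),
and an optional tendency to revisit the previously rewarded alternative.
Every dataset is written together with its ground-truth parameters so
the fitting machinery can be validated by parameter recovery.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .task import (
    DesignSpec,
    Environment,
    SampleAllocation,
    TrialRecord,
    simulate_trial,
)
from . import ideal, models

__all__ = [
    "NoiseSpec",
    "AgentSpec",
    "draw_m",
    "allocate",
    "generate_dataset",
    "parameter_recovery",
]

logger = logging.getLogger(__name__)

SPLIT_RULES = ("homogeneous", "optimal_partition", "random_composition")
SEQUENCE_RULES = ("depth_focused", "breadth_focused", "interleaved_random")
CHOICE_RULES = ("v_norm", "v_prop")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise on the number of sampled alternatives M.

    ``binomial``: M ~ Binomial(n, p) with n = round(mean / p); ``gaussian``:
    M = round(mean + (a + bC) z) with standard normal z.
    """

    kind: str
    p: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "binomial":
            if self.p is None or not 0 < self.p <= 1:
                raise ValueError("binomial noise requires 0 < p <= 1")
        elif self.kind == "gaussian":
            if self.a is None or self.b is None:
                raise ValueError("gaussian noise requires a and b")
        else:
            raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass(frozen=True)
class AgentSpec:
    """Generative parameters of one simulated participant."""

    w: Union[float, Mapping[str, float]]
    noise: NoiseSpec
    split_rule: str = "homogeneous"
    sequence_rule: str = "interleaved_random"
    choice_rule: str = "v_norm"
    lapse: float = 0.0
    resample_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.split_rule not in SPLIT_RULES:
            raise ValueError(f"split_rule must be one of {SPLIT_RULES}")
        if self.sequence_rule not in SEQUENCE_RULES:
            raise ValueError(f"sequence_rule must be one of {SEQUENCE_RULES}")
        if self.choice_rule not in CHOICE_RULES:
            raise ValueError(f"choice_rule must be one of {CHOICE_RULES}")
        if not 0 <= self.lapse <= 1:
            raise ValueError("lapse must lie in [0, 1]")
        if not 0 <= self.resample_bias <= 1:
            raise ValueError("resample_bias must lie in [0, 1]")
        ws = self.w.values() if isinstance(self.w, Mapping) else [self.w]
        if any(w <= 0 for w in ws):
            raise ValueError("power exponent w must be positive")

    def w_for(self, env_label: str) -> float:
        if isinstance(self.w, Mapping):
            return float(self.w[env_label])
        return float(self.w)


def _draw_m_raw(
    agent: AgentSpec, capacity: int, env_label: str, rng: np.random.Generator
) -> int:
    mean = float(capacity) ** agent.w_for(env_label)
    noise = agent.noise
    if noise.kind == "binomial":
        n = max(1, int(round(mean / noise.p)))
        return int(rng.binomial(n, noise.p))
    sigma = noise.a + noise.b * capacity
    if sigma <= 0:
        raise ValueError(f"gaussian noise sigma <= 0 at capacity {capacity}")
    return int(round(rng.normal(mean, sigma)))


def draw_m(
    agent: AgentSpec,
    capacity: int,
    rng: np.random.Generator,
    n_suppliers: Optional[int] = None,
    env_label: str = "neutral",
) -> int:
    """Noisy draw of the number of alternatives to sample, around C^w.

    Clamped to [1, min(capacity, n_suppliers)].
    """
    if capacity < 2:
        raise ValueError("capacity must be >= 2")
    upper = capacity if n_suppliers is None else min(capacity, n_suppliers)
    return int(np.clip(_draw_m_raw(agent, capacity, env_label, rng), 1, upper))


@lru_cache(maxsize=None)
def _best_partition_with_parts(
    capacity: int, m: int, alpha: float, beta: float
) -> Tuple[int, ...]:
    """The expected-reward-maximizing partition of capacity into exactly m parts."""
    best = None
    best_v = -np.inf
    for part in ideal.enumerate_partitions(capacity, m):
        if len(part) != m:
            continue
        v = ideal.expected_max_value(part, Environment("custom", alpha, beta))
        if v > best_v:
            best, best_v = part, v
    assert best is not None
    return best


def _split_counts(
    m: int,
    capacity: int,
    split_rule: str,
    rng: np.random.Generator,
    env: Optional[Environment],
) -> List[int]:
    if split_rule == "homogeneous":
        base, extra = divmod(capacity, m)
        return [base + 1] * extra + [base] * (m - extra)
    if split_rule == "optimal_partition":
        if env is None:
            raise ValueError("optimal_partition split requires an environment")
        return list(_best_partition_with_parts(capacity, m, env.alpha, env.beta))
    if split_rule == "random_composition":
        # uniform composition of capacity into m positive parts (stars & bars)
        cuts = rng.choice(capacity - 1, size=m - 1, replace=False) + 1 if m > 1 else []
        edges = [0, *sorted(cuts), capacity]
        return [edges[i + 1] - edges[i] for i in range(m)]
    raise ValueError(f"unknown split rule {split_rule!r}")


def allocate(
    m: int,
    capacity: int,
    split_rule: str,
    sequence_rule: str,
    rng: np.random.Generator,
    n_suppliers: int,
    env: Optional[Environment] = None,
    previous_choice: Optional[int] = None,
    force_include_previous: bool = False,
) -> SampleAllocation:
    """Build an ordered sample allocation for one trial.

    ``m`` distinct suppliers are drawn at random; counts follow the split
    rule and the allocation order follows the sequence rule.  When
    ``force_include_previous`` is set the previously chosen supplier is
    guaranteed a slot (the resampling-bias mechanism).
    """
    if not 1 <= m <= min(capacity, n_suppliers):
        raise ValueError(f"m={m} infeasible for capacity {capacity}, "
                         f"{n_suppliers} suppliers")
    counts = _split_counts(m, capacity, split_rule, rng, env)
    suppliers = list(rng.choice(n_suppliers, size=m, replace=False))
    if (
        force_include_previous
        and previous_choice is not None
        and previous_choice not in suppliers
    ):
        suppliers[int(rng.integers(m))] = previous_choice
    rng.shuffle(counts)
    pairs = list(zip(suppliers, counts))
    if sequence_rule == "depth_focused":
        seq = [s for s, c in pairs for _ in range(c)]
    elif sequence_rule == "breadth_focused":
        seq = [s for s, _ in pairs]
        remaining = [[s] * (c - 1) for s, c in pairs]
        seq += [s for tup in itertools.zip_longest(*remaining) for s in tup
                if s is not None] if remaining else []
    else:  # interleaved_random
        seq = [s for s, c in pairs for _ in range(c)]
        rng.shuffle(seq)
    return SampleAllocation(tuple(int(s) for s in seq), n_suppliers)


def _choice_rule_for(
    agent: AgentSpec, env: Environment, rng: np.random.Generator
):
    def choose(outcomes: Sequence[int], allocation: SampleAllocation) -> int:
        sampled = sorted(allocation.counts)
        if agent.lapse > 0 and rng.random() < agent.lapse:
            return int(rng.choice(sampled))
        trial_like = _Tally(allocation, outcomes)
        if agent.choice_rule == "v_norm":
            cand = ideal.normative_choice(trial_like, env)
        else:
            cand = ideal.proportional_choice(trial_like)
        cand = sorted(cand)
        return int(cand[0] if len(cand) == 1 else rng.choice(cand))

    return choose


class _Tally:
    """Duck-typed stand-in exposing successes_by_supplier for choice rules."""

    def __init__(self, allocation: SampleAllocation, outcomes: Sequence[int]):
        self.allocation = allocation
        self.outcomes = outcomes

    def successes_by_supplier(self):
        tally: Dict[int, Tuple[int, int]] = {}
        for idx, out in zip(self.allocation.sequence, self.outcomes):
            k, n = tally.get(idx, (0, 0))
            tally[idx] = (k + int(out), n + 1)
        return tally


_WITHIN_ORDERS = list(itertools.permutations(("poor", "neutral", "rich")))


def _agent_env_schedule(
    design: DesignSpec, envs: Optional[Sequence[str]], agent_index: int
) -> Tuple[str, ...]:
    if len(design.env_schedule) == 3:
        # within-subject: counterbalance block order across agents
        return _WITHIN_ORDERS[agent_index % len(_WITHIN_ORDERS)]
    pool = tuple(envs) if envs else ("poor", "neutral", "rich")
    return (pool[agent_index % len(pool)],)


def generate_dataset(
    design: DesignSpec,
    n_agents: int,
    agent: AgentSpec,
    seed: int,
    envs: Optional[Sequence[str]] = None,
) -> Tuple[List[TrialRecord], pd.DataFrame]:
    """Simulate ``n_agents`` full participants under one design.

    Within-subject designs run all three environments in counterbalanced
    block order; between-subject designs assign one environment per
    agent, cycling through ``envs`` (default poor/neutral/rich).  Returns
    the trial records and a ground-truth table (one row per agent,
    including the fraction of clamped M draws).
    """
    rng = np.random.default_rng(seed)
    records: List[TrialRecord] = []
    truth_rows = []
    for ai in range(n_agents):
        pid = f"{design.name}-a{ai:03d}"
        n_clamped = 0
        n_draws = 0
        schedule = _agent_env_schedule(design, envs, ai)
        for block, env_label in enumerate(schedule):
            env = Environment.from_label(env_label)
            choose = _choice_rule_for(agent, env, rng)
            capacities = np.repeat(design.capacity_set,
                                   design.reps_per_capacity_per_env)
            rng.shuffle(capacities)
            prev: Optional[TrialRecord] = None
            for ti, cap in enumerate(capacities):
                cap = int(cap)
                raw = _draw_m_raw(agent, cap, env_label, rng)
                m = int(np.clip(raw, 1, min(cap, design.n_suppliers)))
                n_clamped += int(m != raw)
                n_draws += 1
                force_prev = False
                if (
                    prev is not None
                    and agent.resample_bias > 0
                    and prev.reward > 100 * env.prior_mean
                ):
                    force_prev = rng.random() < agent.resample_bias
                alloc = allocate(
                    m,
                    cap,
                    agent.split_rule,
                    agent.sequence_rule,
                    rng,
                    design.n_suppliers,
                    env=env,
                    previous_choice=prev.chosen_supplier if prev else None,
                    force_include_previous=force_prev,
                )
                rec = simulate_trial(
                    env,
                    cap,
                    alloc,
                    choose,
                    rng,
                    participant_id=pid,
                    design=design.name,
                    block_index=block,
                    trial_index=ti,
                )
                records.append(rec)
                prev = rec
        frac_clamped = n_clamped / n_draws if n_draws else 0.0
        if frac_clamped > 0.25:
            logger.warning(
                "agent %s: %.0f%% of M draws clamped; recovery may be biased",
                pid, 100 * frac_clamped,
            )
        truth_rows.append(
            {
                "participant_id": pid,
                "design": design.name,
                "environments": ";".join(schedule),
                "w": agent.w if not isinstance(agent.w, Mapping)
                else ";".join(f"{k}={v}" for k, v in sorted(agent.w.items())),
                "noise_kind": agent.noise.kind,
                "noise_p": agent.noise.p,
                "noise_a": agent.noise.a,
                "noise_b": agent.noise.b,
                "split_rule": agent.split_rule,
                "sequence_rule": agent.sequence_rule,
                "choice_rule": agent.choice_rule,
                "lapse": agent.lapse,
                "resample_bias": agent.resample_bias,
                "frac_clamped": frac_clamped,
            }
        )
    return records, pd.DataFrame(truth_rows)


def parameter_recovery(
    trials: Sequence[TrialRecord],
    truth: pd.DataFrame,
    grids: Optional[Mapping[str, models.Grid]] = None,
    families: Sequence[str] = models.FAMILIES,
    n_folds: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Fitted parameters and CVLL-selected family joined against the truth.

    Fits use binomial noise (the generator's own noise family in the
    canonical recovery suite).  One row per participant x environment.
    """
    if len(trials) == 0:
        return pd.DataFrame(
            columns=["participant_id", "environment", "true_w", "fitted_w",
                     "true_p", "fitted_p", "selected_family"]
        )
    comparison = models.compare_models(
        trials,
        noise_kinds=("binomial",),
        families=families,
        grids=grids,
        n_folds=n_folds,
        seed=seed,
    )
    power = comparison[comparison["family"] == "free_power"][
        ["participant_id", "environment", "param_w", "param_p"]
    ].rename(columns={"param_w": "fitted_w", "param_p": "fitted_p"})
    selected = models.select_family(comparison)[
        ["participant_id", "environment", "family"]
    ].rename(columns={"family": "selected_family"})
    out = power.merge(selected, on=["participant_id", "environment"])
    tcols = truth[["participant_id", "w", "noise_p"]].rename(
        columns={"w": "true_w", "noise_p": "true_p"}
    )
    out = out.merge(tcols, on="participant_id", how="left")
    return out[
        ["participant_id", "environment", "true_w", "fitted_w",
         "true_p", "fitted_p", "selected_family"]
    ]
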