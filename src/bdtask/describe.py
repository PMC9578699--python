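"""Descriptive statistics of breadth-depth sampling behaviour.

Summaries of the number of alternatives sampled (M) against capacity (C)
and its power-law / linear / piecewise fits, distance from the
ideal-observer policy (both in M and in obtained reward), homogeneity of
sample allocations, order-of-allocation strategy classification,
trial-to-trial resampling effects, and agreement of final choices with
the normative (V_norm) and proportional (V_prop) decision rules.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .task import TrialRecord, Environment
from .ideal import (
    OptimalPolicyEntry,
    normative_choice,
    proportional_choice,
)

__all__ = [
    "PowerFit",
    "tradeoff_curve",
    "power_fit",
    "linear_fit",
    "piecewise_power_fit",
    "deviation_from_optimal",
    "allocation_sd",
    "homogeneity_vs_optimal",
    "outcome_vs_optimal",
    "classify_sequence",
    "strategy_fractions",
    "resampling_stats",
    "choice_agreement",
    "worst_choice_report",
]


def _cm_points(
    data: "Sequence[TrialRecord] | Sequence[Tuple[float, float]]",
) -> Tuple[np.ndarray, np.ndarray]:
    if len(data) and isinstance(data[0], TrialRecord):
        c = np.array([t.capacity for t in data], dtype=float)
        m = np.array([t.allocation.m for t in data], dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        c, m = arr[:, 0], arr[:, 1]
    return c, m


def _r2_adjusted(observed: np.ndarray, fitted: np.ndarray, k: int) -> float:
    n = len(observed)
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if n - k - 1 <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass(frozen=True)
class PowerFit:
    """Zero-intercept power law M = C^a fitted in log-log space."""

    exponent: float
    r2_adj: float
    n_points: int


def tradeoff_curve(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Mean M, s.e.m. and M/C ratio per environment x capacity."""
    df = pd.DataFrame(
        {
            "environment": [t.environment for t in trials],
            "capacity": [t.capacity for t in trials],
            "m": [t.allocation.m for t in trials],
        }
    )
    out = (
        df.groupby(["environment", "capacity"])["m"]
        .agg(mean_m="mean", sem="sem", n_trials="count")
        .reset_index()
    )
    out["ratio"] = out["mean_m"] / out["capacity"]
    return out


def power_fit(
    data: "Sequence[TrialRecord] | Sequence[Tuple[float, float]]",
    per_capacity_means: bool = False,
) -> PowerFit:
    """Fit M = C^a by zero-intercept least squares on log M vs log C.

    The closed-form estimator is ``a = sum(logC * logM) / sum(logC^2)``.
    By default every trial contributes a point; ``per_capacity_means``
    fits the capacity-averaged M instead (sensitivity mode).
    """
    c, m = _cm_points(data)
    if per_capacity_means:
        df = pd.DataFrame({"c": c, "m": m}).groupby("c")["m"].mean().reset_index()
        c, m = df["c"].to_numpy(), df["m"].to_numpy()
    if np.any(m < 1) or np.any(c < 2):
        raise ValueError("power fit requires M >= 1 and C >= 2")
    lc, lm = np.log(c), np.log(m)
    a = float(np.sum(lc * lm) / np.sum(lc * lc))
    return PowerFit(a, _r2_adjusted(lm, a * lc, k=1), len(c))


def linear_fit(
    data: "Sequence[TrialRecord] | Sequence[Tuple[float, float]]",
) -> Tuple[float, float, float]:
    """Least-squares fit of M = aC + b; returns (a, b, adjusted R^2)."""
    c, m = _cm_points(data)
    if len(np.unique(c)) < 2:
        raise ValueError("linear fit needs at least two distinct capacities")
    a, b = np.polyfit(c, m, 1)
    return float(a), float(b), _r2_adjusted(m, a * c + b, k=2)


def piecewise_power_fit(
    data: "Sequence[TrialRecord] | Sequence[Tuple[float, float]]",
    breakpoint_grid: Sequence[int],
) -> Tuple[float, float, float, int, float]:
    """Piecewise power law: M = C^a1 for C <= B, M = C^a2 + b for C > B.

    Fitted by nonlinear least squares on the M scale for each candidate
    breakpoint B; the breakpoint with the smallest residual sum of
    squares wins.  Returns (a1, a2, b, B, adjusted R^2).
    """
    c, m = _cm_points(data)
    best = None
    for bp in breakpoint_grid:
        lo, hi = c <= bp, c > bp
        if lo.sum() < 2 or hi.sum() < 2:
            continue

        def _resid(theta, c=c, m=m, lo=lo, hi=hi):
            # exponents bounded to keep the LM search out of overflow
            a1, a2, b = np.clip(theta[0], -5, 5), np.clip(theta[1], 0, 5), theta[2]
            pred = np.where(lo, c**a1, c**a2 + b)
            return pred - m

        sol = least_squares(_resid, x0=[1.0, 0.5, 0.0], method="lm")
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            a1, a2, b = sol.x
            pred = np.where(lo, c**a1, c ** np.clip(a2, 0, None) + b)
            best = (rss, float(a1), float(a2), float(b), int(bp),
                    _r2_adjusted(m, pred, k=3))
    if best is None:
        raise ValueError("no breakpoint leaves >= 2 capacities on each side")
    return best[1], best[2], best[3], best[4], best[5]


def _policy_lookup(
    policy: "Sequence[OptimalPolicyEntry] | Mapping[str, Sequence[OptimalPolicyEntry]]",
    env_label: str,
) -> Dict[int, OptimalPolicyEntry]:
    if isinstance(policy, Mapping):
        entries = policy[env_label]
    else:
        entries = policy
    return {e.capacity: e for e in entries}


def deviation_from_optimal(
    trials: Sequence[TrialRecord],
    policy: "Sequence[OptimalPolicyEntry] | Mapping[str, Sequence[OptimalPolicyEntry]]",
) -> pd.DataFrame:
    """Per-capacity mean of M_opt - M (positive = sampling deeper than optimal)."""
    rows = []
    for t in trials:
        entry = _policy_lookup(policy, t.environment).get(t.capacity)
        if entry is None:
            raise ValueError(
                f"capacity {t.capacity} missing from optimal policy for "
                f"{t.environment}"
            )
        rows.append(
            {
                "participant_id": t.participant_id,
                "environment": t.environment,
                "capacity": t.capacity,
                "difference": entry.m_opt - t.allocation.m,
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["environment", "capacity"])["difference"]
        .agg(mean_diff="mean", sem="sem", n_trials="count")
        .reset_index()
    )


def allocation_sd(counts: Sequence[int]) -> float:
    """Sample standard deviation (n-1 denominator) of per-alternative counts.

    A single-part allocation returns 0 by convention: e.g.
    sd({2,2}) = 0, sd({2,1,1}) ~ 0.577, sd({1,3}) ~ 1.41.
    """
    counts = list(counts)
    if len(counts) == 0:
        raise ValueError("counts must be non-empty")
    if len(counts) == 1:
        return 0.0
    return float(np.std(counts, ddof=1))


def homogeneity_vs_optimal(
    trials: Sequence[TrialRecord],
    policy: "Sequence[OptimalPolicyEntry] | Mapping[str, Sequence[OptimalPolicyEntry]]",
) -> pd.DataFrame:
    """Per participant x environment: mean allocation-sd difference vs optimal.

    Only trials where the optimal policy itself is not pure breadth
    (M_opt < C) qualify; negative values mean the observed allocations
    are more homogeneous than the optimal ones.
    """
    rows = []
    for t in trials:
        entry = _policy_lookup(policy, t.environment)[t.capacity]
        if entry.m_opt >= t.capacity:
            continue
        rows.append(
            {
                "participant_id": t.participant_id,
                "environment": t.environment,
                "sd_diff": allocation_sd(t.allocation.partition)
                - allocation_sd(entry.best_partition),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["participant_id", "environment", "mean_sd_diff", "n_trials"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["participant_id", "environment"])["sd_diff"]
        .agg(mean_sd_diff="mean", n_trials="count")
        .reset_index()
    )


def outcome_vs_optimal(
    trials: Sequence[TrialRecord],
    policy: "Sequence[OptimalPolicyEntry] | Mapping[str, Sequence[OptimalPolicyEntry]]",
) -> pd.DataFrame:
    """Mean observed reward minus the ideal observer's expected reward.

    Expressed in units of the 100-apricot purchase (percent); restricted,
    like the homogeneity comparison, to trials with M_opt < C.
    """
    rows = []
    for t in trials:
        entry = _policy_lookup(policy, t.environment)[t.capacity]
        if entry.m_opt >= t.capacity:
            continue
        rows.append(
            {
                "participant_id": t.participant_id,
                "environment": t.environment,
                "outcome_diff": t.reward - entry.expected_reward,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["participant_id", "environment", "mean_outcome_diff", "n_trials"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["participant_id", "environment"])["outcome_diff"]
        .agg(mean_outcome_diff="mean", n_trials="count")
        .reset_index()
    )


def classify_sequence(sequence: Sequence[int]) -> str:
    """Classify the allocation order of one trial.

    * ``depth_focused``: every alternative's samples are contiguous
      (each alternative is exhausted before the next is started);
    * ``breadth_focused``: the first M samples touch M distinct
      alternatives (everything is visited once before any revisit);
    * ``mixed``: neither; ``excluded``: pure depth (M = 1) or pure
      breadth (M = C), for which the two strategies are indistinguishable.

    A sequence satisfying both definitions is labelled depth_focused.
    """
    seq = list(sequence)
    m = len(set(seq))
    if m == 1 or m == len(seq):
        return "excluded"
    contiguous = sum(1 for i in range(1, len(seq)) if seq[i] != seq[i - 1]) == m - 1
    if contiguous:
        return "depth_focused"
    if len(set(seq[:m])) == m:
        return "breadth_focused"
    return "mixed"


def strategy_fractions(
    trials: Sequence[TrialRecord], min_trials: int = 10
) -> pd.DataFrame:
    """Fractions of depth-/breadth-focused/mixed trials per (M, C) cell.

    Cells with fewer than ``min_trials`` eligible trials are suppressed.
    """
    rows = []
    for t in trials:
        label = classify_sequence(t.allocation.sequence)
        if label == "excluded":
            continue
        rows.append({"m": t.allocation.m, "capacity": t.capacity, "label": label})
    if not rows:
        return pd.DataFrame(
            columns=["m", "capacity", "n_trials", "depth_focused",
                     "breadth_focused", "mixed"]
        )
    df = pd.DataFrame(rows)
    out = []
    for (m, c), cell in df.groupby(["m", "capacity"]):
        if len(cell) < min_trials:
            continue
        frac = cell["label"].value_counts(normalize=True)
        out.append(
            {
                "m": m,
                "capacity": c,
                "n_trials": len(cell),
                "depth_focused": float(frac.get("depth_focused", 0.0)),
                "breadth_focused": float(frac.get("breadth_focused", 0.0)),
                "mixed": float(frac.get("mixed", 0.0)),
            }
        )
    return pd.DataFrame(out)


def _median_split_high(trials: Sequence[TrialRecord]) -> Dict[Tuple[str, int, int], bool]:
    """Label each trial high (True) / low reward within capacity x environment.

    Ties at the median go to the low bin.
    """
    df = pd.DataFrame(
        {
            "key": [(t.participant_id, t.block_index, t.trial_index) for t in trials],
            "environment": [t.environment for t in trials],
            "capacity": [t.capacity for t in trials],
            "reward": [t.reward for t in trials],
        }
    )
    labels: Dict[Tuple[str, int, int], bool] = {}
    for _, grp in df.groupby(["environment", "capacity"]):
        med = grp["reward"].median()
        for _, r in grp.iterrows():
            labels[r["key"]] = bool(r["reward"] > med)
    return labels


def resampling_stats(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tendency to revisit the previously chosen alternative after reward.

    For consecutive trial pairs within a block, reports per participant
    and previous-reward level (median split within capacity x
    environment, ties low): the probability that the previously chosen
    alternative receives at least one sample, and the mean fraction of
    capacity allocated to it.
    """
    high = _median_split_high(trials)
    by_block: Dict[Tuple[str, int], List[TrialRecord]] = {}
    for t in trials:
        by_block.setdefault((t.participant_id, t.block_index), []).append(t)
    rows = []
    for (pid, block), block_trials in sorted(by_block.items()):
        ordered = sorted(block_trials, key=lambda t: t.trial_index)
        if len(ordered) < 2:
            continue
        for prev, cur in zip(ordered, ordered[1:]):
            counts = cur.allocation.counts
            n_on_prev = counts.get(prev.chosen_supplier, 0)
            rows.append(
                {
                    "participant_id": pid,
                    "prev_reward": "high"
                    if high[(prev.participant_id, prev.block_index, prev.trial_index)]
                    else "low",
                    "resampled": int(n_on_prev > 0),
                    "capacity_fraction": n_on_prev / cur.capacity,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["participant_id", "prev_reward", "p_resample",
                     "mean_capacity_fraction", "n_pairs"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["participant_id", "prev_reward"])
        .agg(
            p_resample=("resampled", "mean"),
            mean_capacity_fraction=("capacity_fraction", "mean"),
            n_pairs=("resampled", "count"),
        )
        .reset_index()
    )


def choice_agreement(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Agreement of final choices with the V_norm and V_prop decision rules.

    A choice agrees when it lies in the rule's argmax set.  On trials
    disagreeing with V_prop, also reports the mean difference in sample
    counts between the chosen alternative and the V_prop-best one
    (positive = the chosen alternative was sampled more).
    """
    rows = []
    for t in trials:
        env = Environment.from_label(t.environment)
        tally = t.successes_by_supplier()
        norm_set = normative_choice(t, env)
        prop_set = proportional_choice(t)
        agrees_prop = t.chosen_supplier in prop_set
        count_diff = np.nan
        if not agrees_prop:
            best_prop = max(prop_set, key=lambda i: tally[i][1])
            count_diff = tally[t.chosen_supplier][1] - tally[best_prop][1]
        rows.append(
            {
                "participant_id": t.participant_id,
                "environment": t.environment,
                "agrees_norm": int(t.chosen_supplier in norm_set),
                "agrees_prop": int(agrees_prop),
                "count_diff": count_diff,
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["participant_id", "environment"])
        .agg(
            frac_norm=("agrees_norm", "mean"),
            frac_prop=("agrees_prop", "mean"),
            mean_count_diff_on_disagree=("count_diff", "mean"),
            n_trials=("agrees_norm", "count"),
        )
        .reset_index()
    )


def worst_choice_report(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Data-quality screen: fraction of trials choosing the worst supplier.

    The worst supplier is the sampled one with the minimum proportional
    outcome (when unique).  High fractions (>= 0.10) flag inattentive
    responding; reported, never auto-filtered.
    """
    rows = []
    for t in trials:
        tally = t.successes_by_supplier()
        if len(tally) < 2:
            continue
        props = {i: k / n for i, (k, n) in tally.items()}
        worst = min(props.values())
        worst_set = {i for i, v in props.items() if v <= worst + 1e-12}
        if len(worst_set) == len(props):
            continue  # all tied: no informative worst
        rows.append(
            {
                "participant_id": t.participant_id,
                "worst_chosen": int(t.chosen_supplier in worst_set),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["participant_id", "frac_worst", "n_trials", "flagged"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("participant_id")
        .agg(frac_worst=("worst_chosen", "mean"), n_trials=("worst_chosen", "count"))
        .reset_index()
    )
    out["flagged"] = out["frac_worst"] >= 0.10
    return out
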