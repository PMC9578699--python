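"""Ideal-observer tests: Beta-Binomial values, partitions, optimal policy."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from bdtask import (
    Environment,
    beta_binomial_pmf,
    enumerate_partitions,
    expected_max_value,
    monte_carlo_expected_value,
    normative_choice,
    optimal_allocation,
    optimal_curve,
    posterior_mean,
    proportional_choice,
    value_distribution,
    SampleAllocation,
    TrialRecord,
)
from bdtask.ideal import count_partitions

ENV_LABELS = ("poor", "neutral", "rich")


class TestBetaBinomial:
    def test_single_sample_success_is_prior_mean(self, poor):
        assert beta_binomial_pmf(1, 1, poor) == pytest.approx(0.25)

    def test_matches_numeric_integration_oracle(self, neutral):
        # integrate C(2,1) p (1-p) against the Beta(3,3) density
        oracle, _ = quad(
            lambda p: 2 * p * (1 - p) * beta_dist.pdf(p, 3, 3), 0, 1
        )
        assert beta_binomial_pmf(1, 2, neutral) == pytest.approx(oracle)
        assert beta_binomial_pmf(1, 2, neutral) == pytest.approx(3 / 7)

    @pytest.mark.parametrize("label", ENV_LABELS)
    @pytest.mark.parametrize("n", [1, 5, 17])
    def test_normalization(self, label, n):
        env = Environment.from_label(label)
        total = sum(beta_binomial_pmf(k, n, env) for k in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_domain_k_rejected(self, poor):
        with pytest.raises(ValueError):
            beta_binomial_pmf(3, 2, poor)


class TestPosteriorMean:
    @pytest.mark.parametrize(
        "k,n,label,expected",
        [
            (0, 0, "poor", 0.25),
            (1, 1, "neutral", 4 / 7),
            (3, 4, "poor", 0.625),
        ],
    )
    def test_worked_values(self, k, n, label, expected):
        env = Environment.from_label(label)
        assert posterior_mean(k, n, env) == pytest.approx(expected)


class TestValueDistribution:
    @pytest.mark.parametrize("label", ENV_LABELS)
    def test_probabilities_normalized_support_increasing(self, label):
        env = Environment.from_label(label)
        dist = value_distribution(6, env)
        assert sum(dist.probs) == pytest.approx(1.0, abs=1e-12)
        assert all(b > a for a, b in zip(dist.support, dist.support[1:]))
        assert all(p >= 0 for p in dist.probs)


class TestExpectedMaxValue:
    def test_two_singleton_parts_neutral_enumeration_oracle(self, neutral):
        # two one-sample parts: values {3/7, 4/7} each w.p. 1/2, independent
        vals = [3 / 7, 4 / 7]
        oracle = np.mean([max(a, b) for a in vals for b in vals])
        assert oracle == pytest.approx(15 / 28)
        assert expected_max_value((1, 1), neutral) == pytest.approx(15 / 28)

    @pytest.mark.parametrize("label", ENV_LABELS)
    @pytest.mark.parametrize("n", [1, 2, 8, 32, 64])
    def test_martingale_single_part_equals_prior_mean(self, label, n):
        env = Environment.from_label(label)
        assert expected_max_value((n,), env) == pytest.approx(
            env.prior_mean, abs=1e-10
        )

    def test_bounded_between_prior_mean_and_max_support(self, rich):
        v = expected_max_value((3, 2, 1), rich)
        top = max(value_distribution(n, rich).support[-1] for n in (3, 2, 1))
        assert rich.prior_mean < v < top

    def test_empty_partition_rejected(self, poor):
        with pytest.raises(ValueError):
            expected_max_value((), poor)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        extra=st.lists(st.integers(min_value=1, max_value=6), max_size=3),
        base=st.integers(min_value=1, max_value=8),
        label=st.sampled_from(ENV_LABELS),
    )
    def test_adding_parts_never_reduces_the_expected_maximum(
        self, extra, base, label
    ):
        env = Environment.from_label(label)
        lo = expected_max_value((base,), env)
        hi = expected_max_value((base, *extra), env)
        assert hi >= lo - 1e-12

    def test_agrees_with_monte_carlo_on_random_partitions(self, rng):
        for label in ENV_LABELS:
            env = Environment.from_label(label)
            for _ in range(4):
                c = int(rng.integers(2, 11))
                parts = list(enumerate_partitions(c, c))
                part = parts[rng.integers(len(parts))]
                exact = expected_max_value(part, env)
                est, se = monte_carlo_expected_value(part, env, 100_000, rng)
                assert abs(exact - est) < 3 * max(se, 1e-9)


class TestEnumeratePartitions:
    def test_capacity_four_canonical_order(self):
        assert list(enumerate_partitions(4, 4)) == [
            (4,), (3, 1), (2, 2), (2, 1, 1), (1, 1, 1, 1)
        ]

    def test_max_parts_restriction(self):
        assert list(enumerate_partitions(5, 2)) == [(5,), (4, 1), (3, 2)]

    def test_counts_match_partition_number_recurrence(self):
        # independent oracle: dp over p(n, k) = partitions with parts <= k
        def p_atmost(n, kmax):
            table = [[0] * (kmax + 1) for _ in range(n + 1)]
            for k in range(kmax + 1):
                table[0][k] = 1
            for i in range(1, n + 1):
                for k in range(1, kmax + 1):
                    table[i][k] = table[i][k - 1] + (
                        table[i - k][k] if i >= k else 0
                    )
            return table[n][kmax]

        # partitions into at most m parts == partitions with parts <= m
        assert count_partitions(32, 32) == p_atmost(32, 32) == 8349
        assert count_partitions(12, 5) == p_atmost(12, 5)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        capacity=st.integers(min_value=1, max_value=14),
        max_parts=st.integers(min_value=1, max_value=14),
    )
    def test_each_partition_unique_valid_and_nonincreasing(self, capacity, max_parts):
        parts = list(enumerate_partitions(capacity, max_parts))
        assert len(parts) == len(set(parts))
        for p in parts:
            assert sum(p) == capacity
            assert 1 <= len(p) <= max_parts
            assert all(a >= b for a, b in zip(p, p[1:]))


class TestOptimalPolicy:
    def test_low_capacity_poor_is_pure_breadth(self, poor):
        entry = optimal_allocation(4, poor, 10)
        assert entry.best_partition == (1, 1, 1, 1)
        assert entry.m_opt == 4

    def test_capacity_two_neutral_prefers_breadth(self, neutral):
        # {1,1} gives 15/28 > 1/2 from {2}
        entry = optimal_allocation(2, neutral, 10)
        assert entry.best_partition == (1, 1)
        assert entry.expected_value == pytest.approx(15 / 28)

    @pytest.mark.parametrize("label", ENV_LABELS)
    def test_feasibility_at_capacity_two(self, label):
        env = Environment.from_label(label)
        entry = optimal_allocation(2, env, 10)
        assert entry.m_opt in (1, 2)
        assert entry.expected_value >= env.prior_mean

    def test_expected_reward_nondecreasing_small_range(self, neutral):
        curve = optimal_curve(neutral, range(2, 13), 12)
        rewards = [e.expected_reward for e in curve]
        assert all(b >= a - 1e-9 for a, b in zip(rewards, rewards[1:]))

    def test_rich_prefers_depth_over_poor(self, poor, rich):
        for c in range(6, 11):
            assert (
                optimal_allocation(c, rich, 10).m_opt
                <= optimal_allocation(c, poor, 10).m_opt
            )


def _trial(tallies, n_suppliers=10):
    """Build a trial whose per-supplier (k, n) tallies match the given dict."""
    seq, outcomes = [], []
    for supplier, (k, n) in tallies.items():
        seq.extend([supplier] * n)
        outcomes.extend([1] * k + [0] * (n - k))
    return TrialRecord(
        "p", "custom", "neutral", 0, 0, len(seq),
        SampleAllocation(tuple(seq), n_suppliers), tuple(outcomes),
        next(iter(tallies)), 50,
    )


class TestChoiceRules:
    def test_normative_prefers_more_sampled_in_poor(self, poor):
        # A: 3 of 4 -> 0.625; B: 1 of 1 -> 4/7: normative picks A
        trial = _trial({0: (3, 4), 1: (1, 1)})
        assert normative_choice(trial, poor) == {0}

    def test_proportional_disagrees_with_normative_in_poor(self):
        trial = _trial({0: (3, 4), 1: (1, 1)})
        assert proportional_choice(trial) == {1}

    def test_identical_tallies_tie(self, poor):
        trial = _trial({0: (2, 3), 1: (2, 3)})
        assert normative_choice(trial, poor) == {0, 1}
        assert proportional_choice(trial) == {0, 1}

    def test_all_bad_ties_everyone(self):
        trial = _trial({0: (0, 2), 1: (0, 3)})
        assert proportional_choice(trial) == {0, 1}

    def test_single_sampled_supplier_returned(self, rich):
        trial = _trial({4: (0, 3)})
        assert normative_choice(trial, rich) == {4}
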