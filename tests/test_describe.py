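"""Descriptive-analysis tests: fits, homogeneity, sequences, agreement."""
import itertools

import numpy as np
import pytest

from bdtask import (
    AgentSpec,
    DESIGNS,
    Environment,
    NoiseSpec,
    SampleAllocation,
    TrialRecord,
    allocation_sd,
    choice_agreement,
    classify_sequence,
    deviation_from_optimal,
    generate_dataset,
    homogeneity_vs_optimal,
    linear_fit,
    outcome_vs_optimal,
    optimal_curve,
    piecewise_power_fit,
    power_fit,
    resampling_stats,
    strategy_fractions,
    tradeoff_curve,
)

NARROW = list(range(2, 11))
FULL = NARROW + [16, 32]


class TestPowerFit:
    def test_pure_breadth_gives_unit_exponent(self):
        fit = power_fit([(c, c) for c in NARROW])
        assert fit.exponent == pytest.approx(1.0)
        assert fit.r2_adj == pytest.approx(1.0)

    def test_exact_recovery_of_power_law(self):
        fit = power_fit([(c, c**0.75) for c in FULL])
        assert fit.exponent == pytest.approx(0.75)

    def test_per_capacity_mean_mode(self):
        pts = [(c, c**0.6) for c in NARROW for _ in range(3)]
        assert power_fit(pts, per_capacity_means=True).exponent == pytest.approx(0.6)

    def test_m_below_one_rejected(self):
        with pytest.raises(ValueError):
            power_fit([(2, 0.5), (3, 2)])


class TestLinearAndPiecewiseFits:
    def test_linear_exact_recovery(self):
        a, b, r2 = linear_fit([(c, 2 * c + 1) for c in NARROW])
        assert (a, b) == (pytest.approx(2.0), pytest.approx(1.0))
        assert r2 == pytest.approx(1.0)

    def test_piecewise_recovers_breakpoint_at_zero_noise(self):
        def w_model(c, a1=1.0, a2=0.5, b=3.0, bp=6):
            return c**a1 if c <= bp else c**a2 + b

        pts = [(c, w_model(c)) for c in FULL for _ in range(2)]
        a1, a2, b, bp, r2 = piecewise_power_fit(pts, range(3, 17))
        assert bp == 6
        assert a1 == pytest.approx(1.0, abs=1e-4)
        assert a2 == pytest.approx(0.5, abs=1e-3)
        assert b == pytest.approx(3.0, abs=1e-3)

    def test_power_beats_linear_on_power_data(self, rng):
        # mirrors the observed ranking on smooth power-law behaviour
        pts = [
            (c, max(1.0, c**0.75 + rng.normal(0, 0.2)))
            for c in NARROW
            for _ in range(8)
        ]
        p_fit = power_fit(pts)
        _, _, r2_lin = linear_fit(pts)
        assert p_fit.r2_adj >= r2_lin - 0.05


class TestAllocationSd:
    @pytest.mark.parametrize(
        "counts,expected",
        [((2, 2), 0.0), ((2, 1, 1), 0.5773502691896257), ((1, 3), 1.4142135623730951)],
    )
    def test_worked_examples(self, counts, expected):
        assert allocation_sd(counts) == pytest.approx(expected)

    def test_single_part_zero_by_convention(self):
        assert allocation_sd((5,)) == 0.0

    def test_most_even_partition_minimizes_sd(self):
        # enumeration oracle over all partitions of C into exactly M parts
        def partitions_exact(n, m, largest=None):
            largest = largest or n
            if m == 1:
                yield (n,) if n <= largest else ()
                return
            for first in range(min(n - m + 1, largest), 0, -1):
                for rest in partitions_exact(n - first, m - 1, first):
                    if rest:
                        yield (first, *rest)

        for c in range(4, 13):
            for m in range(2, c):
                parts = [p for p in partitions_exact(c, m) if p and sum(p) == c]
                base, extra = divmod(c, m)
                most_even = tuple([base + 1] * extra + [base] * (m - extra))
                best = min(parts, key=allocation_sd)
                assert allocation_sd(best) == pytest.approx(
                    allocation_sd(most_even)
                )


def _alloc_trial(seq, pid="p", env="neutral", n_sup=32, reward=50, block=0, trial=0,
                 outcomes=None, chosen=None):
    alloc = SampleAllocation(tuple(seq), n_sup)
    return TrialRecord(
        pid, "custom", env, block, trial, len(seq), alloc,
        outcomes or (0,) * len(seq), chosen if chosen is not None else seq[0],
        reward,
    )


@pytest.fixture(scope="module")
def poor_policy():
    env = Environment.from_label("poor")
    return {"poor": optimal_curve(env, NARROW, 10)}


class TestDeviationAndHomogeneity:

    def test_optimal_replay_gives_zero_everywhere(self, poor_policy):
        trials = []
        for entry in poor_policy["poor"]:
            seq = [
                s for s, n in enumerate(entry.best_partition) for _ in range(n)
            ]
            trials.append(_alloc_trial(seq, env="poor", n_sup=10))
        dev = deviation_from_optimal(trials, poor_policy)
        assert (dev["mean_diff"] == 0).all()
        hom = homogeneity_vs_optimal(trials, poor_policy)
        if len(hom):
            assert (hom["mean_sd_diff"] == 0).all()

    def test_sign_convention_depth_is_positive(self, poor_policy):
        # sampling fewer alternatives than optimal -> M_opt - M > 0
        trials = [_alloc_trial([0] * 8, env="poor", n_sup=10)]
        dev = deviation_from_optimal(trials, poor_policy)
        assert (dev["mean_diff"] > 0).all()

    def test_pure_breadth_trials_excluded_from_homogeneity(self, poor_policy):
        # at capacities where the optimum is pure breadth nothing qualifies
        eligible = {e.capacity for e in poor_policy["poor"] if e.m_opt < e.capacity}
        trials = [
            _alloc_trial(list(range(c)), env="poor", n_sup=10)
            for c in NARROW
            if c not in eligible
        ]
        assert len(homogeneity_vs_optimal(trials, poor_policy)) == 0

    def test_homogeneous_agent_has_negative_sd_difference(self):
        # uneven optima (and hence the homogeneity bias) are clearest in rich
        env = Environment.from_label("rich")
        policy = {"rich": optimal_curve(env, NARROW, 10)}
        trials = []
        for entry in policy["rich"]:
            c, m = entry.capacity, entry.m_opt
            if m >= c:
                continue
            base, extra = divmod(c, m)
            counts = [base + 1] * extra + [base] * (m - extra)
            seq = [s for s, n in enumerate(counts) for _ in range(n)]
            trials.append(_alloc_trial(seq, env="rich", n_sup=10))
        hom = homogeneity_vs_optimal(trials, policy)
        assert (hom["mean_sd_diff"] <= 0).all()
        assert (hom["mean_sd_diff"] < 0).any()

    def test_outcome_vs_optimal_bounded(self, poor_policy):
        trials = [_alloc_trial([0] * 8, env="poor", n_sup=10, reward=100)]
        out = outcome_vs_optimal(trials, poor_policy)
        assert ((out["mean_outcome_diff"] >= -100) &
                (out["mean_outcome_diff"] <= 100)).all()


class TestClassifySequence:
    @pytest.mark.parametrize(
        "seq,label",
        [
            ("aabccdd", "depth_focused"),
            ("abcddac", "breadth_focused"),
            ("ababc", "mixed"),
            ("aaaa", "excluded"),
            ("abcd", "excluded"),
        ],
    )
    def test_worked_examples(self, seq, label):
        mapping = {ch: i for i, ch in enumerate(sorted(set(seq)))}
        assert classify_sequence([mapping[ch] for ch in seq]) == label

    def test_every_sequence_gets_exactly_one_label(self, rng):
        labels = {"depth_focused", "breadth_focused", "mixed", "excluded"}
        for _ in range(200):
            c = int(rng.integers(2, 9))
            seq = rng.integers(0, 4, size=c)
            assert classify_sequence(list(seq)) in labels


class TestStrategyFractions:
    def test_all_depth_agent_fills_cells_with_ones(self):
        trials = []
        for _ in range(12):
            trials.append(_alloc_trial([0, 0, 1, 1, 2]))  # M=3, C=5, depth runs
        table = strategy_fractions(trials, min_trials=10)
        assert len(table) == 1
        assert table.iloc[0]["depth_focused"] == 1.0

    def test_fractions_sum_to_one_and_small_cells_suppressed(self):
        trials = [_alloc_trial([0, 1, 0, 1, 2]) for _ in range(11)]
        trials += [_alloc_trial([0, 0, 1]) for _ in range(5)]  # below threshold
        table = strategy_fractions(trials, min_trials=10)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["depth_focused"] + row["breadth_focused"] + row["mixed"] == 1.0


class TestResampling:
    def test_history_free_agent_shows_no_split_difference(self):
        spec = AgentSpec(w=0.75, noise=NoiseSpec("binomial", p=0.9))
        records, _ = generate_dataset(
            DESIGNS["B32"], 6, spec, seed=21, envs=["neutral"]
        )
        stats = resampling_stats(records)
        assert ((stats["p_resample"] >= 0) & (stats["p_resample"] <= 1)).all()
        assert (
            (stats["mean_capacity_fraction"] >= 0)
            & (stats["mean_capacity_fraction"] <= 1)
        ).all()
        wide = stats.pivot_table(
            index="participant_id", columns="prev_reward", values="p_resample"
        ).dropna()
        # no history dependence: high/low difference stays small on average
        assert abs((wide["high"] - wide["low"]).mean()) < 0.15

    def test_revisit_biased_agent_detectable(self):
        spec = AgentSpec(
            w=0.75, noise=NoiseSpec("binomial", p=0.9), resample_bias=0.9
        )
        records, _ = generate_dataset(
            DESIGNS["B32"], 6, spec, seed=22, envs=["neutral"]
        )
        stats = resampling_stats(records)
        wide = stats.pivot_table(
            index="participant_id", columns="prev_reward", values="p_resample"
        ).dropna()
        assert (wide["high"] - wide["low"]).mean() > 0.05


class TestChoiceAgreement:
    def test_lapse_free_vprop_agent_agrees_fully(self):
        spec = AgentSpec(
            w=0.75, noise=NoiseSpec("binomial", p=0.9), choice_rule="v_prop"
        )
        records, _ = generate_dataset(
            DESIGNS["B10"], 2, spec, seed=9, envs=["poor"]
        )
        table = choice_agreement(records)
        assert (table["frac_prop"] == 1.0).all()

    def test_worked_disagreement_counts_extra_samples(self):
        # A: 3/4 vs B: 1/1 in poor; choosing A agrees with V_norm only
        seq = [0, 0, 0, 0, 1]
        outcomes = (1, 1, 1, 0, 1)
        t = _alloc_trial(seq, env="poor", n_sup=10, outcomes=outcomes, chosen=0)
        table = choice_agreement([t])
        row = table.iloc[0]
        assert row["frac_norm"] == 1.0
        assert row["frac_prop"] == 0.0
        assert row["mean_count_diff_on_disagree"] == 3.0


class TestTradeoffCurve:
    def test_mean_m_bounded_by_capacity(self, small_dataset):
        records, _ = small_dataset
        curve = tradeoff_curve(records)
        assert ((curve["mean_m"] >= 1) & (curve["mean_m"] <= curve["capacity"])).all()
        assert ((curve["ratio"] > 0) & (curve["ratio"] <= 1)).all()
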