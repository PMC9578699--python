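# bdtask — breadth–depth trade-offs in many-alternative sampling

`bdtask` is a Python library for studying how a decision maker should — and
how people actually do — allocate a finite sampling budget across many
alternatives before committing to one of them. It implements the "apricot
supplier" task: on each trial an agent receives a budget of `C` samples
(coins), spends them freely across `N` suppliers whose unknown success
probabilities `p_i` are drawn i.i.d. from a Beta(α, β) environment prior,
observes the Bernoulli(p_i) outcome of every sample, and finally buys 100
units from one sampled supplier, earning Binomial(100, p_chosen) reward.
Spreading the budget widely (breadth) surveys many suppliers superficially;
concentrating it (depth) estimates a few suppliers well. The package is
aimed at computational cognitive scientists who want the exact normative
policy for this problem, a behavioural model-fitting pipeline for trial
data, and a synthetic-agent generator to validate that pipeline end to end.

## What it computes

**Exact ideal observer.** After `k` successes in `n` samples the posterior
mean of a supplier's quality is

    V_norm = (k + α) / (n + α + β),

and `k ~ BetaBinomial(n; α, β)`. The value of a sample *partition*
(n₁, …, n_M) of the budget is the expected maximum of the M independent
posterior-mean distributions, evaluated exactly via the product of their
CDFs on the merged support grid, `P(max ≤ v) = Π_i F_i(v)`. The optimal
policy per capacity is found by exhaustive search over all integer
partitions of `C` (8349 partitions at C = 32); a Monte-Carlo estimator is
kept as an independent cross-check. Three canonical environments are
built in: poor Beta(1/3, 1), neutral Beta(3, 3) and rich Beta(1, 1/3),
with prior means 0.25 / 0.50 / 0.75.

**Behavioural model comparison.** Six families predict the mean number of
sampled alternatives M as a function of capacity — depth (M = 2), pure
breadth (M = C), free-slope linear (dC), square root (√C), free power law
(C^w) and the ideal-observer curve — each combined with binomial or
Gaussian noise, fitted by exhaustive grid search and compared by fourfold
cross-validated log-likelihood (CVLL) and AIC.

**Descriptive analyses.** Breadth–depth trade-off curves and power-law /
linear / piecewise fits, deviation from the optimal M, homogeneity of
sample allocations (s.d. of the per-alternative counts), depth- vs
breadth-focused allocation-order classification, trial-to-trial
resampling statistics, and agreement of final choices with the normative
(`V_norm`) and prior-free proportional (`V_prop = k/n`) rules.

**Synthetic agents.** Parameterized generators (power exponent, noise,
split rule, allocation order, choice rule with lapse, resampling bias)
emit trial tables in the canonical designs — W10, B10, W32, B32 with
capacities 2–10 or {2, 4, 8, 16, 32} and 8 repetitions per capacity per
environment — plus ground-truth files for parameter-recovery checks.
Real trial data in the same CSV schema can be read with
`bdtask.read_trials` and analysed with the identical pipeline.

## Worked example

```python
from bdtask import Environment, optimal_curve, power_fit

env = Environment.from_label("poor")          # Beta(1/3, 1), prior mean 0.25
curve = optimal_curve(env, [2, 3, 4, 5, 6, 7, 8, 9, 10, 16, 32], max_parts=32)
for e in curve[:7]:
    print(e.capacity, e.m_opt, e.best_partition, round(e.expected_value, 4))
fit = power_fit([(e.capacity, e.m_opt) for e in curve])
print("exponent:", round(fit.exponent, 3))
```

prints

```
2 2 (1, 1) 0.3304
3 3 (1, 1, 1) 0.3906
4 4 (1, 1, 1, 1) 0.4358
5 5 (1, 1, 1, 1, 1) 0.4697
6 6 (1, 1, 1, 1, 1, 1) 0.4952
7 6 (2, 1, 1, 1, 1, 1) 0.5157
8 7 (2, 1, 1, 1, 1, 1, 1) 0.5342
exponent: 0.877
```

Up to a budget of 6 the optimal policy in the poor environment is pure
breadth — one sample on as many suppliers as there are coins; from C = 7
on it starts doubling up on a few suppliers. Over the full capacity set
the optimal number of sampled alternatives grows as `M_opt ≈ C^0.877`;
the same computation gives exponents 0.714 (neutral) and 0.612 (rich), so
richer environments favour depth. The scripts in `examples/` walk through
each capability (optimal policy, simulation + description, model
comparison, parameter recovery) with printed, annotated output.

A thin command-line interface mirrors the library:

```bash
bdtask optimal-curve --env poor --capacities 2-10,16,32 --suppliers 32 --out policy.csv
bdtask simulate --design W10 --agents 18 --w 0.75 --noise binomial:0.9 --seed 7 --out trials.csv
bdtask compare-models --trials trials.csv --noise binomial --seed 1 --out cvll.csv
```

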