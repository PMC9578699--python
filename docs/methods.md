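# Methods

## Task model

Each trial gives the agent a budget of `C ≥ 2` samples over `N` suppliers
(10 in the narrow designs, 32 in the wide ones). Supplier qualities
`p_i` are drawn i.i.d. from a Beta(α, β) prior, fresh on every trial.
Every sample placed on supplier `i` returns an independent Bernoulli(p_i)
outcome, so the tally on a supplier that received `n_i` samples is
`X_i ~ Binomial(n_i, p_i)`. After all samples are revealed, exactly one
*sampled* supplier may be chosen; the reward is `Binomial(100, p_chosen)`.
The canonical environments are poor Beta(1/3, 1), neutral Beta(3, 3) and
rich Beta(1, 1/3) (prior means 0.25 / 0.50 / 0.75); custom shapes are
accepted anywhere. The four built-in designs (W10, B10, W32, B32) pair a
capacity set ({2..10} or {2, 4, 8, 16, 32}) with 8 repetitions per
capacity per environment block, giving 216 / 72 / 120 / 40 trials per
participant. Within a block, capacities are presented in a uniformly
shuffled order (the repetition counts are exact; no constraint on
immediate repeats is imposed). Supplier indices are 0-based in memory and
1-based in CSV files; the I/O layer owns the conversion.

## Exact ideal observer

With `k` successes in `n` samples the posterior mean quality is
`(k + α)/(n + α + β)`, and marginally `k ~ BetaBinomial(n; α, β)`. For a
partition `(n_1, …, n_M)` of the budget, the expected reward (per unit)
is the expectation of the maximum of M independent discrete posterior-mean
variables. We compute it exactly: the per-part supports are rounded to
1e-12 and merged into one grid, the maximum's CDF is the product of the
per-part CDFs on that grid, and the expectation is the dot product of the
grid with the differenced CDF. Rounding matters only to merge support
values that coincide across parts (e.g. symmetric priors); 1e-12 is far
below the spacing of distinct Beta-Binomial posterior means at n ≤ 64 and
far above double-precision noise.

The optimal allocation per capacity is an exhaustive argmax over all
integer partitions of `C` with at most `N` parts (8349 partitions at
C = 32), enumerated in canonical non-increasing/lexicographic order.
Exhaustive exact evaluation replaces Monte-Carlo estimation of the same
objective; the Monte-Carlo estimator (`monte_carlo_expected_value`) is
retained purely as an independent oracle and is required, in the test
suite, to agree with the exact values within three standard errors.
Expected values within 1e-12 of each other are treated as ties and broken
deterministically: fewer parts first, then the lexicographically largest
(deepest) partition. Near-ties are real in this problem — at capacity 6
in the poor environment pure breadth `{1,1,1,1,1,1}` beats the best
5-part partition by only 0.0042 in expected unit value, so estimators
with sampling noise can place the breadth-to-depth transition at 6 while
the exact optimum keeps pure breadth through 6 and first departs at 7.
The package reports the exact answer.

Unsampled suppliers never enter the maximum: the task forbids choosing
them, and with `n = 0` their posterior mean is the prior mean, which a
rational agent can always match by the martingale property anyway.

## Final-choice rules

`normative_choice` returns the argmax set of `V_norm = (Σ O + α)/(N_i + α + β)`
over sampled suppliers; `proportional_choice` the argmax set of the
prior-free `V_prop = k_i / n_i`. Both return the full tie set; downstream
agreement statistics count a choice as agreeing when it lies in the set.

## Behavioural model families and likelihoods

Each family predicts the mean number of sampled alternatives:
depth `M(C) = 2`; pure breadth `M(C) = C`; linear `M(C) = dC`;
square root `M(C) = √C`; free power `M(C) = C^w`; optimal
`M(C) = M_opt(C)` looked up from the exact policy for that environment.

Two noise models link the prediction to the observed integer `M`:

* **Gaussian**: `M ~ Normal(M(C) + μ, σ)` with `σ = a + bC`, scored with
  the standard log-density `−½log 2π − log σ − r²/(2σ²)`. Parameter pairs
  implying `σ ≤ 0` at any observed capacity are rejected with −∞.
* **Binomial**: `M ~ Binomial(n, p)` with `n = round((M(C) + μ)/p)`
  clamped to ≥ 1, so the noisy mean matches the model's prediction up to
  rounding (|np − M(C)| ≤ p/2). Observations with `M > n` are impossible
  events and contribute −∞; this is deliberate and drives the
  fold-exclusion rule below.

The offset `μ` defaults to 0 for both noise models and is exposed as an
optional argument. Grids: `w` and `d` on 0.05..1.1 (step 0.05), `p` on
0.01..1 (step 0.01), Gaussian `a` on −3..3 and `b` on −1..1 (step 0.05,
σ-positivity enforced per dataset). The slope `d` shares the exponent
grid because it spans the same behavioural range (from near-depth to
slightly-super-breadth); all grids are overridable programmatically and
via the CLI config file. Grid argmax ties are broken toward the smallest
parameter vector in lexicographic order.

## Cross-validation and model comparison

`cross_validate` splits each participant × environment's trials into four
non-overlapping test sets stratified by capacity (so every training fold
sees every capacity and the model never extrapolates to an unseen
`M(C)`), fits the grid on each 75% training set, and scores the held-out
25%. The CVLL is the mean of the finite fold log-likelihoods; folds made
impossible by the binomial −∞ mechanism are excluded and counted, and a
participant whose folds all fail is flagged rather than silently dropped.
AIC (`2k − 2LL`) is computed from the full-data fit, with `k` counting
the family's free parameters (0 or 1) plus the noise parameters (1
binomial, 2 Gaussian). `select_family` ranks by CVLL and resolves exact
ties toward fewer free parameters, then alphabetically, so a nested
family never displaces its simpler special case on equal evidence.

## Descriptive analyses

* `power_fit` regresses `log M` on `log C` through the origin
  (`a = Σ log C log M / Σ(log C)²`). Trial-level points are the default;
  a flag switches to per-capacity means for sensitivity checks. Adjusted
  R² uses `1 − (1−R²)(n−1)/(n−k−1)`.
* `piecewise_power_fit` fits `M = C^{a1}` below a breakpoint `B` and
  `M = C^{a2} + b` above it, per candidate `B`, keeping the breakpoint
  with the least residual sum of squares on the M scale.
* `allocation_sd` is the n−1 sample standard deviation of the
  per-alternative counts (sd({2,2}) = 0, sd({2,1,1}) ≈ 0.577,
  sd({1,3}) ≈ 1.41); single-part allocations return 0 by convention and
  are excluded from homogeneity comparisons anyway.
* Homogeneity and outcome comparisons against the optimal policy use
  only trials where the optimal allocation is not itself pure breadth
  (`M_opt < C`), since otherwise the observed s.d. can only exceed the
  optimal one.
* `classify_sequence` labels an allocation order depth-focused when every
  alternative's samples are contiguous, breadth-focused when the first M
  samples hit M distinct alternatives, mixed otherwise; pure-depth
  (M = 1) and pure-breadth (M = C) trials are excluded as undecidable. A
  sequence passing both tests is labelled depth-focused; for 1 < M < C
  the two definitions can only coincide on degenerate patterns.
* Median splits (previous-trial reward within capacity × environment)
  send ties to the low bin, deterministically.
* The worst-supplier screen (choosing the minimum-proportion supplier)
  is reported per participant with a 10% flag threshold, never applied
  as an automatic filter.

## Synthetic agents

An agent is a power exponent `w` (optionally per environment), a noise
model, a split rule (homogeneous, optimal-partition, or uniform random
composition), a sequence rule (depth-focused, breadth-focused,
interleaved), a choice rule (`v_norm` or `v_prop`) with lapse ε, and a
resampling bias. `M` is drawn around `C^w` under the agent's noise and
clamped to `[1, min(C, N)]`; the fraction of clamped draws is recorded in
the truth table and a warning is emitted above 25%, because clamping
shifts the effective mean strategy. The lapse chooses uniformly among
sampled alternatives with probability ε, mirroring the small fraction of
non-normative choices typical of human data without modelling their
mechanism. The resampling bias forces the previously chosen supplier
into the sampled set with the given probability after an above-prior-mean
reward. Within-subject designs counterbalance block order over the six
environment permutations; between-subject designs cycle agents through
the requested environments. All randomness flows through one explicit
seeded generator, so a fixed seed reproduces byte-identical CSVs.

### Recovery-suite conditions

The canonical recovery suite simulates 50 agents per condition on the
B10 design (72 trials each, neutral environment):

* **Free-power condition**: `w = 0.75`, binomial `p = 0.9`. Clamping is
  negligible here (≈0.1% of draws), the generating model lies inside the
  fitted class, and both `w` (to the 0.05 grid step) and the family are
  recovered essentially always.
* **Pure-breadth condition**: deterministic `M = C` (binomial `p = 1`).
  This is the definitionally correct pure-breadth generator under this
  noise family: for any `p < 1` the effective mean is
  `round(C/p)·p ≠ C`, and clamping to the task ceiling `M ≤ C` pushes it
  further below `C`, so the data of a "noisy pure-breadth" agent are
  genuinely better described by a linear model with slope just under 1 —
  the selection question becomes ill-posed rather than merely noisy.

What passing recovery shows — and what it does not: the generator shares
the binomial noise family with the fitted models, so recovery validates
the fitting and selection machinery, not the realism of that noise for
human data. The generator is stationary (no learning within or across
blocks, no carry-over between environments) and has no motor costs or
reaction times; analyses targeting those phenomena are exercised on the
synthetic data only for their mechanics.

## Problem sizes and numerical choices

The test suite evaluates the full exact policy for capacities 2–32 in
all three environments (about 30,000 partition evaluations per
environment, shared across tests through caching), checks the
single-alternative martingale to 1e-10 for n ≤ 64, verifies the exact
evaluator against 100,000-draw Monte-Carlo estimates on 20 random
partitions, and runs the 50-agent recovery suite for both conditions.
The chance-level outcome check simulates 100,000 trials. The headline
script (`scripts/acceptance.py`) refits the fixed-intercept power law to
the exact `M_opt(C)` over C ∈ {2..10, 16, 32} with 32 suppliers and
scans capacities upward to locate the poor environment's first departure
from pure breadth; both computations are deterministic.

## Known limitations

* The exhaustive partition search is exact but exponential in spirit;
  capacities far beyond 32 need a smarter search or pruning.
* The Gaussian noise model scores integer observations with a continuous
  density; this matches the fitting convention the families were designed
  for, but the binomial model is the principled choice for counts.
* The generator does not emulate block-order contamination or any
  within-block learning, so sequential analyses on synthetic data can
  only demonstrate null or mechanically injected effects.
* Zero-intercept log-log power fits require `M ≥ 1` (always true here)
  and treat every trial equally; heteroscedasticity across capacities is
  not modelled.
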