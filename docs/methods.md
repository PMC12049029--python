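# Methods

## Model and decision rule

Each arm's response rate carries an independent Beta prior (default the
non-informative Beta(1, 1)); responder counts are binomial, so posteriors
are conjugate Beta updates. Historical control data enters the current
control prior as a power prior: the historical binomial likelihood raised
to a weight `a₀ ∈ [0, 1]`, which for a Beta initial prior yields weighted
pseudo-counts `Beta(α₀ + a₀·s₀, β₀ + a₀·(n₀ − s₀))`. Fractional shape
parameters are kept exactly; weighted counts are never rounded to whole
patients. Only the control arm borrows — each round's experimental therapy
is new, so its prior stays non-informative unless explicitly overridden.

Success in a round means `P(p_e − p_c ≥ δ) ≥ γ` under the joint posterior,
with the boundary counting as success. Defaults: margin δ = 0.15
(clinically meaningful improvement) and certainty γ = 0.60, a deliberately
permissive phase II threshold that favours carrying effective therapies
forward over rejecting them.

## Tail probability of a rate difference

`P(p_e − p_c ≥ δ)` for independent Beta variables is computed as

```
P = F_c(max(0, −δ))  +  ∫ f_c(p) · S_e(p + δ) dp
```

over the interval where the integrand is smooth, where `f_c` is the
control posterior density and `S_e` the experimental survival function.
Two routes share this formula:

- **Scalar** (`prob_diff_at_least`): adaptive quadrature
  (`scipy.integrate.quad`, absolute tolerance 1e-10), used by the
  per-round analysis and sensitivity tables.
- **Vectorised** (`prob_diff_matrix`): a fixed 2001-node Gauss–Legendre
  rule evaluated for whole grids of posterior parameter pairs at once,
  used by the enumeration and simulation paths where thousands of pairs
  share one margin.

Both are verified in the test suite against closed forms
(`P(U₂ − U₁ ≥ δ) = (1 − δ)²/2`; the Beta(2,1)-vs-uniform case 2/3) and
against paired Monte-Carlo sampling oracles up to 10⁷ draws, and against
each other. Integrable endpoint singularities (shape parameters below 1)
are handled by the adaptive route; posteriors arising from the bundled
designs always have shapes ≥ 1.

## Operating characteristics

The operating characteristic of a scenario is the frequentist probability,
over current-round data simulated at stated true rates, that the posterior
success rule fires. Two estimators are provided:

- `simulate_oc`: draws both arms' responder counts per replicate
  (10,000 replicates by default, the reference design's own simulation
  size) and reports the success proportion with its binomial Monte-Carlo
  standard error. Because only the two responder counts vary, the rule is
  pre-evaluated on the full discrete outcome grid and replicates are
  table lookups.
- `exact_oc`: sums the product of the two arms' binomial pmfs over every
  outcome pair whose posterior meets the rule — deterministic, zero
  Monte-Carlo error. Refused above 10⁶ grid cells (far beyond any
  realistic phase II arm sizes).

Historical control data in a scenario is **held fixed** at stated
realisations (e.g. the 40% planning realisations 26/63 and 7/16) while the
current round's arms are re-drawn — the reading under which the bundled
design's published percentages reproduce. Re-simulating the historical
arms each replicate at their planning rates is available as the
`resimulate_history` switch on `simulate_oc`; on the bundled scenarios it
shifts the estimates by roughly one to two percentage points.

Scenario grids are Cartesian products of control rates × rate differences
× certainty levels × borrowing weights, with every permutation of the
earlier rounds' planning control rates crossed with the current round's
rate. Grid defaults follow the reference design: control rates
{40, 50, 60}%, differences {−10, 0, +15, +25} pp, certainties
{50, 60, 70, 80}%, weights {0.5, 0.75}. A difference pushing the
experimental rate outside [0, 1] is rejected rather than clipped.

Planning realisations of a closed control arm are derived with **ceiling
rounding** of `n·rate` (fuzzed by 1e-9 against floating-point noise): that
is the convention reproducing the reference design's printed pairs
(40% of 63 → 26/63; 40% of 16 → 7/16), which half-up rounding would not.

Randomness: one user seed spawns an independent `SeedSequence` substream
per scenario (and per acceptance target), so any subset of a grid
reproduces the full run row for row. Within a replicate the control count
is drawn before the experimental count.

## Effective sample size

The control information in a later round is `n_current + Σ a₀ᵢ·n₀ᵢ`,
reported both exactly (63.25 for 16 concurrent controls borrowing 63 at
0.75) and rounded to the nearest patient (63). For the third round both
readings are exposed — mirroring the second round's calculation (63.25) or
counting both prior control arms (16 + 0.75·79 = 75.25) — since either can
be meant by a "63-patient" effective size quoted for later rounds; the
`ess` subcommand prints the both-arms figure per round.

## Governance analytics

Drift review is **descriptive only** — no hypothesis tests. Response-rate
drift is the difference of posterior mean rates (Beta(1,1) priors on each
round's control arm); covariate drift is the absolute standardized
difference, `|m₁ − m₂| / sqrt((s₁² + s₂²)/2)` for continuous covariates
and the same pooled-variance form per level for categorical ones, with the
worst level reported. The default flag threshold of 0.2 is the
conventional imbalance cutoff and is configuration, not a trial rule; the
weighting decision itself remains with the monitoring committee — the
package assembles the evidence record (drift report, chosen weight,
rationale, standard-of-care changes, recruitment gap) and never adjusts
weights on its own.

Weight-sensitivity reanalysis re-runs the round analysis over a grid of
borrowing weights; the weight-0 row coincides exactly with the
concurrent-only analysis and the weight-1 row with full pooling.
Posterior intervals throughout are equal-tailed (central) 95% intervals.

## Synthetic data

`generate_trial_data` emulates one round's patient table: per-arm
Bernoulli responses at stated true rates plus baseline covariates (default
one age-like normal variable, mean 62, sd 10, and one three-level
prior-treatment-lines variable at proportions 0.5/0.3/0.2 — typical of a
relapsed/refractory lymphoma population, and needed only to exercise the
drift reports). It does not model accrual over time, dropout, missing
outcome assessments, response-assessment error, or covariate-outcome
dependence; passing tests therefore demonstrate the arithmetic and the
operating characteristics of the design under ideal binomial sampling, not
robustness to those real-data features.

## Numerical and scale choices

- Simulation sizes: operating-characteristic checks use 10,000 replicates
  (the reference design's size); sampling-oracle cross-checks use 10⁵–10⁷
  draws depending on the tolerance being certified; the test suite's
  property checks run on reduced designs (12–24 patients per arm) where
  exact enumeration is instantaneous.
- Stochastic assertions compare simulation to exact enumeration within 3
  Monte-Carlo standard errors under fixed seeds.
- Degenerate inputs: empty binomial data (0/0) leaves priors unchanged;
  empty concurrent arms are rejected in the round analysis; margins of ±1
  short-circuit to the closed-form answers 1 and 0.

## Known limitations

- Allocation ratios are design metadata; no randomisation mechanism
  (blocks, stratification) is modelled, and no interim analyses exist.
- Borrowing is static power-prior weighting: dynamic/commensurate priors
  and hierarchical borrowing are out of scope.
- Endpoints are binary only; time-to-event outcomes are not handled.
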