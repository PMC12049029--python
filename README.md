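# powerprior

Design and analysis tools for sequential platform trials with a binary
endpoint in which later rounds borrow earlier rounds' control-arm data
through **power priors**.

The package targets the statistician planning or running a phase II
platform trial: several experimental therapies evaluated one after another
("rounds"), each against a concurrent control arm, with the control data
from closed rounds down-weighted and re-used so later rounds need fewer
concurrent controls.

## The model

Each arm's response rate `p` carries a Beta prior and the responder count
is binomial, so the posterior after observing `s` responders in `n`
patients is conjugate:

```
p | s, n  ~  Beta(α + s, β + n − s)
```

Historical control data `D₀ = (s₀, n₀)` enters the current round's control
prior as a power prior — the historical likelihood raised to a borrowing
weight `a₀ ∈ [0, 1]` times an initial prior:

```
π(p | D₀, a₀)  ∝  L(D₀ | p)^a₀ · π₀(p)  =  Beta(α₀ + a₀·s₀, β₀ + a₀·(n₀ − s₀))
```

`a₀ = 1` is full pooling, `a₀ = 0` discards the history; the bundled
three-round design prespecifies `a₀ = 0.75` (sensitivity setting 0.5). The
experimental arm never borrows. A round declares success when

```
P( p_e − p_c ≥ δ | data )  ≥  γ        (δ = 0.15, γ = 0.60 by default)
```

with the tail probability of the difference of two independent Beta
posteriors computed by one-dimensional quadrature to well below 1e-6
absolute error. Operating characteristics — the probability of declaring
success under stated true rates — come either from Monte-Carlo simulation
(10,000 replicates by default) or exactly, by enumerating the discrete
outcome grid and summing binomial probabilities.

The bundled reference design: Round 1 randomises 63 + 63 patients 1:1;
Rounds 2 and 3 randomise 16 control + 63 experimental patients 1:4 while
borrowing all earlier control arms (284 patients in total: 95 control,
189 experimental; the later rounds' effective control sample size at
weight 0.75 is 16 + 0.75·63 = 63.25 ≈ 63 patients).

## Worked example

A Round-2 analysis: 7/16 concurrent control responders, 41/63 experimental
responders, borrowing the Round-1 control arm (26/63) at weight 0.75:

```bash
powerprior analyze --control 7/16 --experimental 41/63 \
    --history 26/63 --weight 0.75 --out analysis.json
# P(diff >= 0.15) = 0.8114; SUCCESS at certainty 0.6
```

The control power prior is Beta(1 + 0.75·26, 1 + 0.75·37) = Beta(20.5,
28.75), updated with 7/16 to Beta(27.5, 37.75); the experimental posterior
is Beta(42, 23). There is an 81% posterior probability that the
experimental arm's true response rate exceeds the control's by at least 15
percentage points, which clears the 60% certainty threshold: the therapy
would be flagged for further investigation. `analysis.json` holds the full
record (posterior parameters, means, central 95% intervals, decision).

Effective sample sizes for the bundled design:

```bash
powerprior ess --config src/powerprior/configs/r3.yaml --out ess.json
# R1: 63 concurrent controls, ESS 63 (~63 patients)
# R2: 16 concurrent controls, ESS 63.25 (~63 patients)
# R3: 16 concurrent controls, ESS 75.25 (~75 patients)
```

Other subcommands: `oc` (simulate a scenario grid to CSV), `sensitivity`
(reanalysis across borrowing weights), `drift` (descriptive control-drift
report across rounds), `simulate-data` (synthetic patient-level CSV). The
same functionality is available as a library:

```python
from powerprior import Scenario, DecisionRule, exact_oc
from powerprior.design import ROUND_1

oc = exact_oc(Scenario(ROUND_1, 0.40, 0.65, rule=DecisionRule(0.15, 0.60)))
print(oc.prob_success)   # 0.7840... — Round 1 OC at true rates 40% vs 65%
```

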