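"""Three-round platform design, scenario grids, and operating characteristics.

The design under study: Round 1 randomises 63 + 63 patients 1:1; Rounds 2
and 3 randomise 16 control + 63 experimental patients 1:4, borrowing the
earlier rounds' control data through a power prior at a prespecified weight
(0.75, with 0.5 as the sensitivity setting).  Operating characteristics are
the frequentist probability, over repeated trials at stated true response
rates, that the posterior success rule fires.  They are computed either by
Monte-Carlo simulation (the trial's own procedure, 10,000 replicates) or
exactly by enumerating the discrete outcome grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import (
    UNIFORM_PRIOR,
    BetaParams,
    BinomialOutcome,
    DecisionRule,
    WeightedOutcome,
    beta_posterior,
    decide_success,
    power_prior,
    prob_diff_at_least,
    prob_diff_matrix,
)

__all__ = [
    "RoundDesign",
    "Scenario",
    "OCResult",
    "RoundAnalysis",
    "build_scenario_grid",
    "historical_counts_for_rate",
    "simulate_oc",
    "exact_oc",
    "oc_table",
    "round_analysis",
    "ROUND_1",
    "ROUND_2",
    "ROUND_3",
    "design_totals",
]

_ENUMERATION_CELL_BOUND = 1_000_000


@dataclass(frozen=True)
class RoundDesign:
    """Per-round arm sizes, allocation ratio, and historical control sources.

    ``history`` lists the earlier rounds' control arms as weighted outcomes;
    the outcome counts act as planning placeholders (a scenario supplies the
    counts actually fixed in simulation), while the weights are the
    borrowing specification.
    """

    round_id: str
    n_control: int
    n_experimental: int
    allocation: tuple[int, int] = (1, 1)
    history: tuple[WeightedOutcome, ...] = ()

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_experimental < 0:
            raise ValueError("arm sizes must be non-negative")

    def with_weight(self, weight: float) -> "RoundDesign":
        """Copy of the design with every historical source at one weight."""
        new_hist = tuple(WeightedOutcome(h.outcome, weight) for h in self.history)
        return replace(self, history=new_hist)


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation study.

    ``historical_fixed_counts`` pins the prior rounds' control data (one
    outcome per design history source) while the current round's arms are
    re-drawn each replicate at the stated true rates.
    """

    design: RoundDesign
    true_control_rate: float
    true_experimental_rate: float
    historical_fixed_counts: tuple[BinomialOutcome, ...] = ()
    rule: DecisionRule = DecisionRule()
    historical_rates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for r in (self.true_control_rate, self.true_experimental_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"true rates must lie in [0, 1], got {r}")
        if len(self.historical_fixed_counts) != len(self.design.history):
            raise ValueError(
                "historical_fixed_counts must align one-to-one with design.history"
            )

    def control_prior(self) -> BetaParams:
        """Power prior for the control arm from the fixed historical counts."""
        hist = [
            WeightedOutcome(counts, h.weight)
            for counts, h in zip(self.historical_fixed_counts, self.design.history)
        ]
        return power_prior(UNIFORM_PRIOR, hist)


@dataclass(frozen=True)
class OCResult:
    """Estimated probability of declaring success, with its precision."""

    prob_success: float
    reps: int
    mc_se: float
    method: Literal["simulation", "exact_enumeration"]


@dataclass(frozen=True)
class RoundAnalysis:
    """The per-round primary-outcome analysis record."""

    control_posterior: BetaParams
    experimental_posterior: BetaParams
    control_mean: float
    experimental_mean: float
    control_interval: tuple[float, float]
    experimental_interval: tuple[float, float]
    prob_diff: float
    margin: float
    certainty: float
    success: bool

    def to_dict(self) -> dict:
        return {
            "control_posterior": {
                "alpha": self.control_posterior.alpha,
                "beta": self.control_posterior.beta,
            },
            "experimental_posterior": {
                "alpha": self.experimental_posterior.alpha,
                "beta": self.experimental_posterior.beta,
            },
            "control_mean": self.control_mean,
            "experimental_mean": self.experimental_mean,
            "control_interval": list(self.control_interval),
            "experimental_interval": list(self.experimental_interval),
            "prob_diff": self.prob_diff,
            "margin": self.margin,
            "certainty": self.certainty,
            "success": self.success,
        }


def _round1() -> RoundDesign:
    return RoundDesign("R1", 63, 63, (1, 1))


def _round2(weight: float = 0.75) -> RoundDesign:
    return RoundDesign(
        "R2",
        16,
        63,
        (1, 4),
        history=(WeightedOutcome(BinomialOutcome(0, 63), weight),),
    )


def _round3(weight: float = 0.75) -> RoundDesign:
    return RoundDesign(
        "R3",
        16,
        63,
        (1, 4),
        history=(
            WeightedOutcome(BinomialOutcome(0, 63), weight),
            WeightedOutcome(BinomialOutcome(0, 16), weight),
        ),
    )


ROUND_1 = _round1()
ROUND_2 = _round2()
ROUND_3 = _round3()


def design_totals(designs: Sequence[RoundDesign] = (ROUND_1, ROUND_2, ROUND_3)) -> dict:
    """Total patients across rounds, split by arm."""
    n_control = sum(d.n_control for d in designs)
    n_experimental = sum(d.n_experimental for d in designs)
    return {
        "control": n_control,
        "experimental": n_experimental,
        "total": n_control + n_experimental,
    }


def historical_counts_for_rate(n: int, rate: float) -> BinomialOutcome:
    """Responder count a planning rate implies for a closed control arm.

    Uses ceiling rounding of ``n * rate`` (fuzzed against floating-point
    noise), the convention that maps 40% of 63 to 26/63 and 40% of 16 to
    7/16 — the counts the design documents quote.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    responders = int(math.ceil(n * rate - 1e-9))
    return BinomialOutcome(min(responders, n), n)


def build_scenario_grid(
    control_rates: Sequence[float],
    differences: Sequence[float],
    certainties: Sequence[float],
    weights: Sequence[float],
    designs: Sequence[RoundDesign],
    margin: float = 0.15,
) -> list[Scenario]:
    """Cartesian scenario grid over rates, effect sizes, certainties, weights.

    For designs with historical sources, every permutation of the preceding
    rounds' planning control rates and the current round's true control rate
    is generated; historical counts are fixed at the rate's implied
    realisation via :func:`historical_counts_for_rate`.  Combinations
    pushing the experimental rate outside [0, 1] are rejected.
    """
    scenarios: list[Scenario] = []
    for design, weight, certainty, diff in itertools.product(
        designs, weights, certainties, differences
    ):
        weighted = design.with_weight(weight)
        n_hist = len(weighted.history)
        for rates in itertools.product(control_rates, repeat=n_hist + 1):
            hist_rates, control_rate = rates[:-1], rates[-1]
            exp_rate = control_rate + diff
            if not (0.0 <= exp_rate <= 1.0):
                raise ValueError(
                    f"difference {diff} puts the experimental rate at {exp_rate}, "
                    "outside [0, 1]"
                )
            hist_counts = tuple(
                historical_counts_for_rate(h.outcome.total, r)
                for h, r in zip(weighted.history, hist_rates)
            )
            scenarios.append(
                Scenario(
                    design=weighted,
                    true_control_rate=control_rate,
                    true_experimental_rate=exp_rate,
                    historical_fixed_counts=hist_counts,
                    rule=DecisionRule(margin, certainty),
                    historical_rates=hist_rates,
                )
            )
    return scenarios


def _success_matrix(scenario: Scenario) -> np.ndarray:
    """Boolean (n_c+1, n_e+1) grid: does outcome (s_c, s_e) fire the rule?"""
    d = scenario.design
    prior_c = scenario.control_prior()
    sc = np.arange(d.n_control + 1)
    se = np.arange(d.n_experimental + 1)
    probs = prob_diff_matrix(
        prior_c.alpha + sc,
        prior_c.beta + d.n_control - sc,
        UNIFORM_PRIOR.alpha + se,
        UNIFORM_PRIOR.beta + d.n_experimental - se,
        scenario.rule.margin,
    )
    return probs >= scenario.rule.certainty


def simulate_oc(
    scenario: Scenario,
    reps: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    resimulate_history: bool = False,
) -> OCResult:
    """Monte-Carlo operating characteristic of the posterior success rule.

    Each replicate draws the current round's responder counts from their
    binomial laws, forms the control power prior from the fixed historical
    counts, updates both arms, and applies the success rule.  With
    ``resimulate_history`` the prior rounds' control data is re-drawn each
    replicate at ``historical_rates`` instead of being held fixed.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = np.random.default_rng(seed)
    d = scenario.design

    if not resimulate_history:
        success = _success_matrix(scenario)
        sc = rng.binomial(d.n_control, scenario.true_control_rate, size=reps)
        se = rng.binomial(d.n_experimental, scenario.true_experimental_rate, size=reps)
        n_success = int(success[sc, se].sum())
    else:
        if len(scenario.historical_rates) != len(d.history):
            raise ValueError(
                "resimulate_history requires historical_rates for every source"
            )
        n_success = 0
        cache: dict[tuple, bool] = {}
        hist_ns = [h.outcome.total for h in d.history]
        hist_ws = [h.weight for h in d.history]
        hist_draws = [
            rng.binomial(n, r, size=reps)
            for n, r in zip(hist_ns, scenario.historical_rates)
        ]
        sc_draws = rng.binomial(d.n_control, scenario.true_control_rate, size=reps)
        se_draws = rng.binomial(
            d.n_experimental, scenario.true_experimental_rate, size=reps
        )
        for i in range(reps):
            key = (tuple(h[i] for h in hist_draws), sc_draws[i], se_draws[i])
            hit = cache.get(key)
            if hit is None:
                prior_c = power_prior(
                    UNIFORM_PRIOR,
                    [
                        WeightedOutcome(BinomialOutcome(int(s), n), w)
                        for s, n, w in zip(key[0], hist_ns, hist_ws)
                    ],
                )
                post_c = beta_posterior(
                    prior_c, BinomialOutcome(int(sc_draws[i]), d.n_control)
                )
                post_e = beta_posterior(
                    UNIFORM_PRIOR, BinomialOutcome(int(se_draws[i]), d.n_experimental)
                )
                p = prob_diff_at_least(post_c, post_e, scenario.rule.margin)
                hit = decide_success(p, scenario.rule)
                cache[key] = hit
            n_success += hit

    p_hat = n_success / reps
    return OCResult(
        prob_success=p_hat,
        reps=reps,
        mc_se=math.sqrt(p_hat * (1.0 - p_hat) / reps),
        method="simulation",
    )


def exact_oc(scenario: Scenario) -> OCResult:
    """Exact operating characteristic by enumerating the outcome grid.

    Sums the product of the two arms' binomial pmfs over every outcome pair
    whose posterior meets the rule.  Deterministic, zero Monte-Carlo error.
    """
    d = scenario.design
    n_cells = (d.n_control + 1) * (d.n_experimental + 1)
    if n_cells > _ENUMERATION_CELL_BOUND:
        raise ValueError(
            f"outcome grid has {n_cells} cells, above the enumeration bound"
        )
    success = _success_matrix(scenario)
    wc = stats.binom.pmf(
        np.arange(d.n_control + 1), d.n_control, scenario.true_control_rate
    )
    we = stats.binom.pmf(
        np.arange(d.n_experimental + 1),
        d.n_experimental,
        scenario.true_experimental_rate,
    )
    p = float(wc @ success @ we)
    return OCResult(
        prob_success=min(1.0, max(0.0, p)),
        reps=0,
        mc_se=0.0,
        method="exact_enumeration",
    )


def oc_table(
    grid: Iterable[Scenario],
    reps: int = 10_000,
    seed: int = 0,
    method: Literal["simulation", "exact_enumeration"] = "simulation",
) -> pd.DataFrame:
    """Operating-characteristics table, one row per scenario.

    A single user seed spawns an independent substream per scenario, so any
    subset of the grid reproduces the full run's values row for row.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("scenario grid is empty")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(grid))
    rows = []
    for i, (scenario, stream) in enumerate(zip(grid, streams)):
        try:
            if method == "simulation":
                res = simulate_oc(scenario, reps=reps, seed=stream)
            else:
                res = exact_oc(scenario)
        except Exception as exc:  # annotate which cell failed
            raise RuntimeError(
                f"scenario {i} (round {scenario.design.round_id}, "
                f"control {scenario.true_control_rate}, "
                f"experimental {scenario.true_experimental_rate}) failed"
            ) from exc
        d = scenario.design
        rows.append(
            {
                "round": d.round_id,
                "hist_rates": ";".join(f"{r:g}" for r in scenario.historical_rates),
                "hist_counts": ";".join(
                    f"{c.responders}/{c.total}"
                    for c in scenario.historical_fixed_counts
                ),
                "true_control_rate": scenario.true_control_rate,
                "true_exp_rate": scenario.true_experimental_rate,
                "difference": round(
                    scenario.true_experimental_rate - scenario.true_control_rate, 12
                ),
                "weight": d.history[0].weight if d.history else float("nan"),
                "margin": scenario.rule.margin,
                "certainty": scenario.rule.certainty,
                "reps": res.reps,
                "seed": seed,
                "method": res.method,
                "prob_success": res.prob_success,
                "mc_se": res.mc_se,
            }
        )
    return pd.DataFrame(rows)


def round_analysis(
    control_data: BinomialOutcome,
    experimental_data: BinomialOutcome,
    history: Sequence[WeightedOutcome],
    rule: DecisionRule,
    control_prior: BetaParams = UNIFORM_PRIOR,
    experimental_prior: BetaParams = UNIFORM_PRIOR,
) -> RoundAnalysis:
    """The per-round primary-outcome analysis.

    Builds the control power prior from ``history``, updates both arms with
    the concurrent data, and evaluates the posterior success rule.  Only the
    control arm borrows; the experimental prior stays non-informative unless
    overridden.
    """
    if control_data.total == 0 or experimental_data.total == 0:
        raise ValueError("concurrent arms must contain patients")
    prior_c = power_prior(control_prior, history)
    post_c = beta_posterior(prior_c, control_data)
    post_e = beta_posterior(experimental_prior, experimental_data)
    prob = prob_diff_at_least(post_c, post_e, rule.margin)
    return RoundAnalysis(
        control_posterior=post_c,
        experimental_posterior=post_e,
        control_mean=post_c.mean,
        experimental_mean=post_e.mean,
        control_interval=post_c.interval(0.95),
        experimental_interval=post_e.interval(0.95),
        prob_diff=prob,
        margin=rule.margin,
        certainty=rule.certainty,
        success=decide_success(prob, rule),
    )
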