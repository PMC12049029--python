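"""Trial-conduct analytics around the borrowing-weight decision.

Before each later-round analysis the data monitoring committee reviews the
historical and concurrent control arms side by side: response-rate drift on
posterior means, and baseline-covariate imbalance as absolute standardized
differences.  The comparison is purely descriptive — no hypothesis tests —
and the weighting decision itself stays with the committee; this module
only assembles the evidence record and runs the prespecified
weight-sensitivity reanalyses.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .bayes import (
    UNIFORM_PRIOR,
    BetaParams,
    BinomialOutcome,
    DecisionRule,
    WeightedOutcome,
    beta_posterior,
)
from .design import RoundAnalysis, round_analysis

__all__ = [
    "ContinuousSummary",
    "CategoricalSummary",
    "ControlSummary",
    "DriftReport",
    "drift_report",
    "weight_sensitivity",
    "weighting_decision_record",
    "standardized_difference",
]


@dataclass(frozen=True)
class ContinuousSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class CategoricalSummary:
    proportions: Mapping[str, float]
    n: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"category proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class ControlSummary:
    """One round's control arm: outcome data plus baseline covariates."""

    round_id: str
    outcome: BinomialOutcome
    covariates: Mapping[str, ContinuousSummary | CategoricalSummary] = field(
        default_factory=dict
    )
    prior: BetaParams = UNIFORM_PRIOR

    @property
    def posterior(self) -> BetaParams:
        return beta_posterior(self.prior, self.outcome)

    @property
    def posterior_rate(self) -> float:
        return self.posterior.mean

    def posterior_interval(self, level: float = 0.95) -> tuple[float, float]:
        return self.posterior.interval(level)


def standardized_difference(
    a: ContinuousSummary | CategoricalSummary,
    b: ContinuousSummary | CategoricalSummary,
) -> float:
    """Absolute standardized difference between two groups' covariate summaries.

    Continuous: |m1 - m2| / sqrt((s1^2 + s2^2) / 2).  Categorical: each level
    is treated as a binary indicator with the same pooled-variance formula
    and the largest level-wise value is reported.  Returns 0 when both
    groups are constant and identical; infinity when means differ with zero
    pooled variance.
    """
    if type(a) is not type(b):
        raise ValueError("covariate types differ between rounds")
    if isinstance(a, ContinuousSummary):
        pooled = math.sqrt((a.sd**2 + b.sd**2) / 2.0)
        diff = abs(a.mean - b.mean)
        if pooled == 0.0:
            return 0.0 if diff == 0.0 else math.inf
        return diff / pooled
    keys = set(a.proportions) | set(b.proportions)
    worst = 0.0
    for k in keys:
        p1 = a.proportions.get(k, 0.0)
        p2 = b.proportions.get(k, 0.0)
        pooled = math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
        diff = abs(p1 - p2)
        if pooled == 0.0:
            val = 0.0 if diff == 0.0 else math.inf
        else:
            val = diff / pooled
        worst = max(worst, val)
    return worst


@dataclass(frozen=True)
class PairwiseDrift:
    round_a: str
    round_b: str
    rate_difference: float  # posterior mean of b minus a
    covariate_std_differences: Mapping[str, float]
    rate_flagged: bool
    covariates_flagged: Mapping[str, bool]


@dataclass(frozen=True)
class DriftReport:
    """Descriptive control-drift comparison for committee review."""

    pairs: tuple[PairwiseDrift, ...]
    flag_threshold: float

    @property
    def any_flagged(self) -> bool:
        return any(
            p.rate_flagged or any(p.covariates_flagged.values()) for p in self.pairs
        )

    def to_dict(self) -> dict:
        return {
            "flag_threshold": self.flag_threshold,
            "any_flagged": self.any_flagged,
            "pairs": [
                {
                    "round_a": p.round_a,
                    "round_b": p.round_b,
                    "rate_difference": p.rate_difference,
                    "rate_flagged": p.rate_flagged,
                    "covariate_std_differences": dict(p.covariate_std_differences),
                    "covariates_flagged": dict(p.covariates_flagged),
                }
                for p in self.pairs
            ],
        }


def drift_report(
    summaries: Sequence[ControlSummary], flag_threshold: float = 0.2
) -> DriftReport:
    """Pairwise control-arm drift across rounds.

    Rate drift is the difference of posterior mean response rates; covariate
    drift is the absolute standardized difference.  A flag marks any
    absolute value exceeding ``flag_threshold``.  Descriptive only.
    """
    if len(summaries) < 2:
        raise ValueError("drift comparison needs at least two rounds")
    if flag_threshold < 0:
        raise ValueError("flag threshold must be non-negative")
    schema = set(summaries[0].covariates)
    for s in summaries[1:]:
        if set(s.covariates) != schema:
            raise ValueError(
                f"covariate schema of round {s.round_id} does not match "
                f"round {summaries[0].round_id}"
            )
    pairs = []
    for a, b in itertools.combinations(summaries, 2):
        rate_diff = b.posterior_rate - a.posterior_rate
        std = {
            name: standardized_difference(a.covariates[name], b.covariates[name])
            for name in schema
        }
        pairs.append(
            PairwiseDrift(
                round_a=a.round_id,
                round_b=b.round_id,
                rate_difference=rate_diff,
                covariate_std_differences=std,
                rate_flagged=abs(rate_diff) > flag_threshold,
                covariates_flagged={k: v > flag_threshold for k, v in std.items()},
            )
        )
    return DriftReport(pairs=tuple(pairs), flag_threshold=flag_threshold)


def weight_sensitivity(
    control_data: BinomialOutcome,
    experimental_data: BinomialOutcome,
    history: Sequence[BinomialOutcome],
    weights: Sequence[float],
    rule: DecisionRule,
) -> pd.DataFrame:
    """Prespecified reanalysis of one round across a grid of borrowing weights.

    One row per weight, ordered by weight: the control power-prior
    parameters, posterior probability of the margin being met, and the
    decision.  Weight 0 reproduces the concurrent-only analysis; weight 1
    the fully pooled one.
    """
    if not weights:
        raise ValueError("weight grid is empty")
    rows = []
    for w in sorted(weights):
        hist = [WeightedOutcome(h, w) for h in history]
        res: RoundAnalysis = round_analysis(control_data, experimental_data, hist, rule)
        prior_alpha = UNIFORM_PRIOR.alpha + sum(w * h.responders for h in history)
        prior_beta = UNIFORM_PRIOR.beta + sum(w * h.nonresponders for h in history)
        rows.append(
            {
                "weight": w,
                "prior_alpha": prior_alpha,
                "prior_beta": prior_beta,
                "control_post_alpha": res.control_posterior.alpha,
                "control_post_beta": res.control_posterior.beta,
                "control_mean": res.control_mean,
                "experimental_mean": res.experimental_mean,
                "prob_diff": res.prob_diff,
                "success": res.success,
            }
        )
    return pd.DataFrame(rows)


def weighting_decision_record(
    report: DriftReport,
    chosen_weight: float,
    rationale: str,
    care_change_note: str = "",
    recruitment_gap_days: float = 0.0,
) -> dict:
    """Serializable weighting-decision record for committee sign-off.

    Bundles the drift evidence with the chosen weight and the justification
    fields (rationale, standard-of-care changes, time between rounds'
    recruitment closures).  The choice itself is the committee's.
    """
    if not (0.0 <= chosen_weight <= 1.0):
        raise ValueError(f"chosen weight must lie in [0, 1], got {chosen_weight}")
    if not rationale or not rationale.strip():
        raise ValueError("a rationale for the chosen weight is required")
    record = {
        "chosen_weight": chosen_weight,
        "rationale": rationale,
        "care_change_note": care_change_note,
        "recruitment_gap_days": recruitment_gap_days,
        "drift_report": report.to_dict(),
    }
    json.dumps(record)  # guarantee serializability
    return record
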