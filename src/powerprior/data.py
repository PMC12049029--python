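"""Synthetic patient-level trial data and aggregation.

The design's inputs are aggregate responder counts; this module supplies a
minimal patient-level carrier around them so the governance summaries
(baseline covariates, side-by-side control comparison) can be exercised.
Default covariates: one age-like continuous variable and one three-level
prior-treatment-lines-like categorical variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import BinomialOutcome
from .design import RoundDesign
from .governance import CategoricalSummary, ContinuousSummary, ControlSummary

__all__ = [
    "CovariateSpec",
    "DEFAULT_COVARIATES",
    "generate_trial_data",
    "aggregate",
    "patient_frame",
    "read_patient_csv",
    "write_patient_csv",
]

PATIENT_COLUMNS = ["patient_id", "round_id", "arm", "response"]


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution parameters for one synthetic baseline covariate.

    ``kind`` is "continuous" (normal with ``mean``/``sd``) or "categorical"
    (levels with given proportions).
    """

    kind: str
    mean: float = 0.0
    sd: float = 1.0
    levels: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError("categorical covariates need level proportions")
            total = sum(self.levels.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"level proportions must sum to 1, got {total}")
        elif self.sd < 0:
            raise ValueError("sd must be non-negative")


DEFAULT_COVARIATES: dict[str, CovariateSpec] = {
    "age": CovariateSpec("continuous", mean=62.0, sd=10.0),
    "prior_lines": CovariateSpec(
        "categorical", levels={"2": 0.5, "3": 0.3, "4+": 0.2}
    ),
}


def generate_trial_data(
    design: RoundDesign,
    true_control_rate: float,
    true_experimental_rate: float,
    covariate_spec: Mapping[str, CovariateSpec] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate one round's patient table.

    Exactly ``n_control + n_experimental`` rows; per-arm Bernoulli responses
    at the stated true rates; covariates from the spec.  Deterministic under
    a fixed seed.
    """
    for r in (true_control_rate, true_experimental_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"true rates must lie in [0, 1], got {r}")
    spec = DEFAULT_COVARIATES if covariate_spec is None else dict(covariate_spec)
    for name, cs in spec.items():
        if not isinstance(cs, CovariateSpec):
            raise ValueError(f"covariate {name!r} is not a CovariateSpec")
    rng = np.random.default_rng(seed)
    n = design.n_control + design.n_experimental
    arms = ["control"] * design.n_control + ["experimental"] * design.n_experimental
    rates = np.where(
        np.array(arms) == "control", true_control_rate, true_experimental_rate
    )
    rows = {
        "patient_id": [f"{design.round_id}-{i + 1:04d}" for i in range(n)],
        "round_id": [design.round_id] * n,
        "arm": arms,
        "response": rng.binomial(1, rates),
    }
    for name, cs in spec.items():
        if cs.kind == "continuous":
            rows[name] = rng.normal(cs.mean, cs.sd, size=n)
        else:
            levels = list(cs.levels)
            probs = [cs.levels[k] for k in levels]
            rows[name] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(rows)


def patient_frame(records: pd.DataFrame | Sequence[Mapping]) -> pd.DataFrame:
    """Coerce patient records to a validated DataFrame."""
    df = pd.DataFrame(records)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table is missing columns {missing}")
    if df.empty:
        raise ValueError("patient table is empty")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dupes[:5]}")
    bad_arm = set(df["arm"]) - {"control", "experimental"}
    if bad_arm:
        raise ValueError(f"unknown arm labels: {sorted(bad_arm)}")
    if not df["response"].isin([0, 1]).all():
        raise ValueError("response must be coded 0/1")
    return df


def _summarize_covariates(
    df: pd.DataFrame,
) -> dict[str, ContinuousSummary | CategoricalSummary]:
    out: dict[str, ContinuousSummary | CategoricalSummary] = {}
    for col in df.columns:
        if col in PATIENT_COLUMNS:
            continue
        series = df[col]
        n = len(series)
        if pd.api.types.is_numeric_dtype(series):
            out[col] = ContinuousSummary(
                mean=float(series.mean()),
                sd=float(series.std(ddof=1)) if n > 1 else 0.0,
                n=n,
            )
        else:
            props = series.value_counts(normalize=True).to_dict()
            out[col] = CategoricalSummary(
                proportions={str(k): float(v) for k, v in props.items()}, n=n
            )
    return out


def aggregate(
    records: pd.DataFrame | Sequence[Mapping],
) -> dict[str, dict[str, BinomialOutcome | ControlSummary]]:
    """Aggregate patient records to per-round, per-arm responder counts.

    Returns ``{round_id: {"control": BinomialOutcome, "experimental":
    BinomialOutcome, "control_summary": ControlSummary}}``; the control
    summary carries the covariate summaries needed for drift review.
    Rejects empty arms.
    """
    df = patient_frame(records)
    result: dict[str, dict] = {}
    for round_id, round_df in df.groupby("round_id", sort=False):
        entry: dict = {}
        for arm in ("control", "experimental"):
            arm_df = round_df[round_df["arm"] == arm]
            if arm_df.empty:
                raise ValueError(f"round {round_id} has an empty {arm} arm")
            entry[arm] = BinomialOutcome(
                int(arm_df["response"].sum()), int(len(arm_df))
            )
        control_df = round_df[round_df["arm"] == "control"]
        entry["control_summary"] = ControlSummary(
            round_id=str(round_id),
            outcome=entry["control"],
            covariates=_summarize_covariates(control_df),
        )
        result[str(round_id)] = entry
    return result


def write_patient_csv(df: pd.DataFrame, path) -> None:
    patient_frame(df).to_csv(path, index=False)


def read_patient_csv(path) -> pd.DataFrame:
    return patient_frame(pd.read_csv(path))
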