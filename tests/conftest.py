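import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from powerprior import (
    BinomialOutcome,
    DecisionRule,
    Scenario,
    WeightedOutcome,
)
from powerprior.design import ROUND_1, ROUND_2, ROUND_3

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Published planning counts: 40% realisations of the 63- and 16-patient
# control arms.
R1_CONTROL_COUNTS = BinomialOutcome(26, 63)
R2_CONTROL_COUNTS = BinomialOutcome(7, 16)


@pytest.fixture
def rule():
    return DecisionRule(margin=0.15, certainty=0.60)


@pytest.fixture
def r1_scenario(rule):
    """Round 1 at true rates 40% control / 65% experimental."""
    return Scenario(ROUND_1, 0.40, 0.65, rule=rule)


@pytest.fixture
def r2_scenario(rule):
    """Round 2 borrowing the fixed 26/63 history at weight 0.75."""
    return Scenario(
        ROUND_2, 0.40, 0.65, (R1_CONTROL_COUNTS,), rule, historical_rates=(0.40,)
    )


@pytest.fixture
def r3_scenario(rule):
    """Round 3 borrowing 26/63 and 7/16 at weight 0.75."""
    return Scenario(
        ROUND_3,
        0.40,
        0.65,
        (R1_CONTROL_COUNTS, R2_CONTROL_COUNTS),
        rule,
        historical_rates=(0.40, 0.40),
    )


def mc_prob_diff(control, experimental, margin, draws=100_000, seed=0):
    """Sampling oracle for P(p_e - p_c >= margin): paired Beta draws."""
    rng = np.random.default_rng(seed)
    pc = rng.beta(control.alpha, control.beta, size=draws)
    pe = rng.beta(experimental.alpha, experimental.beta, size=draws)
    p = float(np.mean(pe - pc >= margin))
    se = np.sqrt(max(p * (1 - p), 1.0 / draws) / draws)
    return p, se
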