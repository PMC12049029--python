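"""Scenario grids, operating characteristics, and the per-round analysis."""

import numpy as np
import pytest

from powerprior import (
    BetaParams,
    BinomialOutcome,
    DecisionRule,
    RoundDesign,
    Scenario,
    WeightedOutcome,
    build_scenario_grid,
    design_totals,
    exact_oc,
    historical_counts_for_rate,
    oc_table,
    prob_diff_at_least,
    round_analysis,
    simulate_oc,
)
from powerprior.design import ROUND_1, ROUND_2

from .conftest import R1_CONTROL_COUNTS, R2_CONTROL_COUNTS, mc_prob_diff


@pytest.mark.parametrize(
    "n, rate, expected",
    [
        (63, 0.40, 26),
        (16, 0.40, 7),
        (63, 0.0, 0),
        (63, 0.60, 38),
        (16, 0.50, 8),
        (63, 1.0, 63),
    ],
)
def test_historical_counts_match_planning_tables(n, rate, expected):
    out = historical_counts_for_rate(n, rate)
    assert out == BinomialOutcome(expected, n)


class TestScenarioGrid:
    def test_round1_grid_size(self, rule):
        grid = build_scenario_grid(
            [0.40, 0.60], [-0.10, 0.0, 0.15, 0.25], [0.60], [0.0], [ROUND_1]
        )
        assert len(grid) == 8
        assert all(not s.historical_rates for s in grid)

    def test_empty_differences_give_empty_grid(self):
        assert build_scenario_grid([0.4], [], [0.6], [0.75], [ROUND_1]) == []

    def test_round2_rate_permutations(self):
        grid = build_scenario_grid(
            [0.40, 0.50, 0.60], [0.25], [0.60], [0.75], [ROUND_2]
        )
        # 3 historical x 3 current control rates for a single (diff, certainty, weight)
        assert len(grid) == 9
        combos = {(s.historical_rates[0], s.true_control_rate) for s in grid}
        assert len(combos) == 9
        for s in grid:
            assert s.historical_fixed_counts[0] == historical_counts_for_rate(
                63, s.historical_rates[0]
            )

    def test_rejects_difference_outside_unit_interval(self):
        with pytest.raises(ValueError):
            build_scenario_grid([0.9], [0.25], [0.6], [0.0], [ROUND_1])


class TestSimulateOC:
    def test_deterministic_under_seed(self, r1_scenario):
        a = simulate_oc(r1_scenario, reps=2000, seed=42)
        b = simulate_oc(r1_scenario, reps=2000, seed=42)
        assert a == b
        assert a.mc_se == pytest.approx(
            np.sqrt(a.prob_success * (1 - a.prob_success) / 2000)
        )

    def test_rejects_nonpositive_reps(self, r1_scenario):
        with pytest.raises(ValueError):
            simulate_oc(r1_scenario, reps=0)

    def test_margin_minus_one_always_succeeds(self):
        s = Scenario(ROUND_1, 0.4, 0.4, rule=DecisionRule(-1.0, 0.6))
        assert simulate_oc(s, reps=500, seed=1).prob_success == 1.0

    def test_zero_experimental_rate_never_succeeds(self):
        s = Scenario(ROUND_1, 0.4, 0.0, rule=DecisionRule(0.15, 0.6))
        assert simulate_oc(s, reps=500, seed=1).prob_success == 0.0
        assert exact_oc(s).prob_success == pytest.approx(0.0, abs=1e-12)

    def test_resimulated_history_is_deterministic_and_close_to_fixed(
        self, r2_scenario
    ):
        a = simulate_oc(r2_scenario, reps=2000, seed=9, resimulate_history=True)
        b = simulate_oc(r2_scenario, reps=2000, seed=9, resimulate_history=True)
        assert a == b
        fixed = exact_oc(r2_scenario).prob_success
        # re-drawing the 40%-rate history adds noise but not systematic shift
        assert abs(a.prob_success - fixed) < 0.08


class TestExactOC:
    def test_agrees_with_simulation(self, r1_scenario, r2_scenario):
        for scen in (r1_scenario, r2_scenario):
            exact = exact_oc(scen)
            sim = simulate_oc(scen, reps=10_000, seed=7)
            assert exact.mc_se == 0.0
            assert abs(exact.prob_success - sim.prob_success) <= 3 * sim.mc_se

    def test_degenerate_rates_reduce_to_single_outcome(self, rule):
        s = Scenario(ROUND_1, 0.0, 1.0, rule=rule)
        # only outcome: 0/63 vs 63/63 -> certain success
        assert exact_oc(s).prob_success == pytest.approx(1.0, abs=1e-12)

    def test_zero_certainty_always_succeeds(self):
        s = Scenario(ROUND_1, 0.4, 0.4, rule=DecisionRule(0.15, 0.0))
        assert exact_oc(s).prob_success == pytest.approx(1.0, abs=1e-12)

    def test_rejects_huge_outcome_grids(self, rule):
        big = RoundDesign("big", 2000, 2000)
        with pytest.raises(ValueError):
            exact_oc(Scenario(big, 0.4, 0.65, rule=rule))

    def test_monotone_in_experimental_rate(self, rule):
        small = RoundDesign("s", 12, 12)
        vals = [
            exact_oc(Scenario(small, 0.4, pe, rule=rule)).prob_success
            for pe in np.linspace(0.1, 0.9, 9)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_antitone_in_certainty(self):
        vals = [
            exact_oc(
                Scenario(ROUND_1, 0.4, 0.65, rule=DecisionRule(0.15, c))
            ).prob_success
            for c in (0.50, 0.60, 0.70, 0.80)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_scenario_ordering_in_effect_size(self, rule):
        """Control-superior < clinically-meaningful < large difference."""
        for pc in (0.40, 0.50, 0.60):
            oc = [
                exact_oc(Scenario(ROUND_1, pc, pc + d, rule=rule)).prob_success
                for d in (-0.10, 0.15, 0.25)
            ]
            assert oc[0] < oc[1] < oc[2]

    def test_full_borrowing_beats_no_borrowing_at_large_effect(self, rule):
        """Borrowing same-rate history sharpens the control posterior."""
        hist_counts = (R1_CONTROL_COUNTS,)
        for w, expect_gain in ((1.0, True),):
            design = ROUND_2.with_weight(w)
            borrowed = exact_oc(
                Scenario(design, 0.40, 0.65, hist_counts, rule, (0.40,))
            ).prob_success
            none = exact_oc(
                Scenario(ROUND_2.with_weight(0.0), 0.40, 0.65, hist_counts, rule, (0.40,))
            ).prob_success
            assert borrowed >= none


class TestOCTable:
    def test_structure_and_determinism(self, rule):
        grid = build_scenario_grid(
            [0.40, 0.60], [-0.10, 0.0, 0.15, 0.25], [0.60], [0.0], [ROUND_1]
        )
        t1 = oc_table(grid, reps=1000, seed=5)
        t2 = oc_table(grid, reps=1000, seed=5)
        assert len(t1) == 8
        assert t1["prob_success"].between(0, 1).all()
        assert t1.equals(t2)
        assert list(t1.columns) == [
            "round", "hist_rates", "hist_counts", "true_control_rate",
            "true_exp_rate", "difference", "weight", "margin", "certainty",
            "reps", "seed", "method", "prob_success", "mc_se",
        ]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            oc_table([], reps=10, seed=0)

    def test_higher_weight_raises_oc_when_history_matches(self, rule):
        rows = []
        for w in (0.5, 0.75):
            scen = Scenario(
                ROUND_2.with_weight(w), 0.40, 0.65,
                (R1_CONTROL_COUNTS,), rule, (0.40,),
            )
            rows.append(oc_table([scen], method="exact_enumeration").iloc[0])
        assert rows[1]["prob_success"] > rows[0]["prob_success"]


class TestRoundAnalysis:
    def test_round1_worked_example(self, rule):
        res = round_analysis(
            BinomialOutcome(26, 63), BinomialOutcome(41, 63), [], rule
        )
        assert res.control_posterior == BetaParams(27, 38)
        assert res.experimental_posterior == BetaParams(42, 23)
        expected = prob_diff_at_least(BetaParams(27, 38), BetaParams(42, 23), 0.15)
        assert res.prob_diff == pytest.approx(expected, abs=1e-12)
        assert res.success is (res.prob_diff >= 0.60)
        lo, hi = res.control_interval
        assert 0 <= lo < res.control_mean < hi <= 1

    def test_identical_arms_never_meet_positive_margin(self, rule):
        res = round_analysis(
            BinomialOutcome(26, 63), BinomialOutcome(26, 63), [], rule
        )
        assert res.prob_diff < 0.5
        assert res.success is False

    def test_extreme_separation_with_borrowing(self, rule):
        res = round_analysis(
            BinomialOutcome(0, 16),
            BinomialOutcome(63, 63),
            [WeightedOutcome(R1_CONTROL_COUNTS, 0.75)],
            rule,
        )
        oracle, se = mc_prob_diff(
            res.control_posterior, res.experimental_posterior, 0.15,
            draws=1_000_000, seed=2,
        )
        assert res.prob_diff > 0.99
        assert abs(res.prob_diff - oracle) <= max(3 * se, 1e-4)
        assert res.success is True

    def test_rejects_empty_concurrent_arms(self, rule):
        with pytest.raises(ValueError):
            round_analysis(BinomialOutcome(0, 0), BinomialOutcome(1, 2), [], rule)


def test_design_totals_match_planned_recruitment():
    totals = design_totals()
    assert totals == {"control": 95, "experimental": 189, "total": 284}
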