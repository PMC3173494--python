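"""Cycle mechanics, discounting, closed-form toys, and the expectation oracle."""

import math

import numpy as np
import pytest

from copdsim import (
    advance_cycle,
    cohort_expectation,
    discount_factor,
    init_cohort,
    initial_distribution,
    make_toy_parameters,
    simulate_cohort,
)
from copdsim.cohort import PatientState
from copdsim.parameters import SmokingStatus, Stage


class TestDiscounting:
    @pytest.mark.parametrize(
        "cycle, rate, expected",
        [(0, 0.035, 1.0), (5, 0.0, 1.0), (1, 0.035, 1 / 1.035), (2, 0.05, 1.05**-2)],
    )
    def test_factor(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected, abs=1e-12)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035)

    def test_shifted_schedule_discounts_first_cycle(self):
        assert discount_factor(0, 0.035, from_cycle_one=True) == pytest.approx(1 / 1.035)


class TestAdvanceCycle:
    def test_dead_patient_rejected(self, geometric_params):
        dead = PatientState(age=50, stage=Stage.DEAD, smoking=SmokingStatus.SMOKER, alive=False)
        with pytest.raises(ValueError):
            advance_cycle(dead, geometric_params, np.random.default_rng(0))

    def test_inert_cycle_accrues_full_year(self):
        p = make_toy_parameters("geometric", death_q=0.0, utility=1.0, cost=0.0)
        s = PatientState(age=40, stage=Stage.GOLD1, smoking=SmokingStatus.SMOKER)
        new, (ly, util, cost) = advance_cycle(s, p, np.random.default_rng(0))
        assert (ly, util, cost) == (1.0, 1.0, 0.0)
        assert new.age == 41 and new.stage == Stage.GOLD1 and new.alive

    def test_gold4_cannot_progress(self, default_params):
        """A GOLD4 patient surviving a cycle stays GOLD4: no next stage exists."""
        rng = np.random.default_rng(1)
        s = PatientState(age=60, stage=Stage.GOLD4, smoking=SmokingStatus.SMOKER)
        survived = 0
        for _ in range(500):
            new, _ = advance_cycle(s, default_params, rng)
            if new.alive:
                survived += 1
                assert new.stage == Stage.GOLD4
        assert survived > 0

    def test_exacerbation_frequency_matches_stage_rate(self, default_params):
        """GOLD2 patients exacerbate in ~39.45% of cycles.

        Inferred from one-cycle mean utility of a GOLD2 cohort, which mixes
        the stable and exacerbated utilities in the exacerbation proportion.
        """
        p = default_params
        cohort = init_cohort(100_000, p, stratum="GOLD2", seed=9)
        out = simulate_cohort(cohort, p, seed=10, turnover=False, horizon=1)
        u_stable, u_exac = p.utility[Stage.GOLD2]
        freq = (u_stable - out.mean_qalys) / (u_stable - u_exac)
        assert freq == pytest.approx(0.3945, abs=0.005)


class TestClosedForms:
    def test_geometric_lifetime_oracle_exact(self):
        """Expected life-years of a constant-hazard patient equal 1/q."""
        for q in (0.25, 0.2, 0.5):
            p = make_toy_parameters("geometric", death_q=q)
            exp = cohort_expectation(p, initial_distribution(p, "GOLD1"))
            assert exp.life_years == pytest.approx(1 / q, abs=1e-9)
            assert exp.qalys == pytest.approx(1 / q, abs=1e-9)

    def test_geometric_lifetime_monte_carlo_within_3se(self, geometric_params):
        cohort = init_cohort(50_000, geometric_params, stratum="GOLD1", seed=11)
        out = simulate_cohort(cohort, geometric_params, seed=12, collect_per_year=False)
        se = out.sd_life_years / math.sqrt(out.n)
        assert abs(out.mean_life_years - 5.0) <= 3 * se

    def test_one_cycle_lifetime_under_full_cycle_accrual(self):
        p = make_toy_parameters("geometric", death_q=1.0, utility=0.7, cost=100.0)
        cohort = init_cohort(200, p, stratum="GOLD1", seed=13)
        out = simulate_cohort(cohort, p, seed=14)
        assert out.mean_life_years == 1.0
        assert out.mean_qalys == pytest.approx(0.7)
        assert out.mean_cost == pytest.approx(100.0)
        assert out.sd_life_years == 0.0

    def test_two_stage_occupancy_closed_form(self):
        """With no death, stage-2 occupancy at cycle t is 1 - (1-p)^t."""
        prog = 0.1
        p = make_toy_parameters("two-stage", progression_p=prog, max_age=40 + 80)
        exp = cohort_expectation(p, initial_distribution(p, "GOLD1"), horizon=50)
        t = np.arange(51)
        expected = 1 - (1 - prog) ** t
        assert exp.stage_occupancy[:, Stage.GOLD2] == pytest.approx(expected, abs=1e-9)

    def test_turnover_reaches_stationary_smoker_fraction(self):
        """Quit/relapse two-state chain settles at 0.026/(0.026+0.047)."""
        p = make_toy_parameters(
            "geometric", death_q=0.0, quit_prob=0.047, relapse_prob=0.026,
            max_age=40 + 400,
        )
        exp = cohort_expectation(p, initial_distribution(p, "GOLD1"), horizon=300)
        last = exp.per_year.iloc[-1]
        stationary = 0.026 / (0.026 + 0.047)
        assert last.smokers / last.alive == pytest.approx(stationary, abs=1e-9)
        # Monte-Carlo route converges to the same equilibrium
        cohort = init_cohort(20_000, p, stratum="GOLD1", seed=15)
        out = simulate_cohort(cohort, p, seed=16, horizon=300)
        mc_last = out.per_year.iloc[-1]
        assert mc_last.smokers / mc_last.alive == pytest.approx(stationary, abs=0.012)


class TestInvariants:
    def test_occupancy_conservation(self, default_params):
        dist = initial_distribution(default_params, "ALL")
        exp = cohort_expectation(default_params, dist)
        totals = exp.stage_occupancy.sum(axis=1)
        assert np.all(np.abs(totals - 1.0) < 1e-9)
        assert exp.stage_occupancy[-1, Stage.DEAD] == pytest.approx(1.0, abs=1e-9)

    def test_stage_never_decreases(self, default_params):
        cohort = init_cohort(300, default_params, seed=17)
        out = simulate_cohort(cohort, default_params, seed=18, collect_traces=True)
        trace = out.per_patient.attrs["stage_trace"]
        assert np.all(np.diff(trace, axis=0) >= 0)

    def test_qalys_bounded_by_life_years_and_discounting_shrinks(self, default_params):
        cohort = init_cohort(5_000, default_params, seed=19)
        out = simulate_cohort(cohort, default_params, seed=20)
        assert 0 <= out.mean_qalys <= out.mean_life_years
        assert out.mean_cost <= out.mean_cost_undiscounted
        assert out.mean_life_years <= out.mean_life_years_undiscounted
        assert out.mean_qalys <= out.mean_qalys_undiscounted

    def test_ex_smokers_outlive_smokers(self, default_params):
        cohort = init_cohort(20_000, default_params, seed=21)
        smokers = simulate_cohort(cohort, default_params, seed=22, turnover=False)
        quit = cohort.copy()
        quit["smoking"] = int(SmokingStatus.EX_SMOKER)
        ex = simulate_cohort(quit, default_params, seed=22, turnover=False)
        assert ex.mean_life_years >= smokers.mean_life_years

    def test_deterministic_given_cohort_and_seed(self, default_params):
        cohort = init_cohort(2_000, default_params, seed=23)
        a = simulate_cohort(cohort, default_params, seed=24)
        b = simulate_cohort(cohort, default_params, seed=24)
        assert (a.mean_cost, a.mean_life_years, a.mean_qalys) == (
            b.mean_cost, b.mean_life_years, b.mean_qalys,
        )

    def test_empty_cohort_rejected(self, default_params):
        import pandas as pd

        with pytest.raises(ValueError):
            simulate_cohort(
                pd.DataFrame(columns=["id", "age", "stage", "smoking", "alive"]),
                default_params, seed=0,
            )
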