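"""Named experiments: burden of smoking, intervention grid, sensitivity suite.

Three families of paired comparisons are provided.

* **Burden of continuous smoking** — a cohort of continuous smokers versus
  the identical cohort as sustained quitters; smoking turnover is disabled
  in both arms so the contrast isolates smoking status itself.
* **Reference-case intervention and its grid** — the "no intervention"
  cohort (all smokers at entry, background turnover of quit 0.047 / relapse
  0.026 active) versus an intervention cohort in which a fraction of
  patients (the initial abstinence rate) is switched to ex-smoker at entry;
  turnover stays active in both arms, so fresh quitters may relapse.  The
  grid crosses abstinence rates {1, 1/3, 1/6, 1/12} with programme costs
  {0, 100, 200, 500, 1000} GBP; each cost re-prices the same simulated
  deltas.
* **Sensitivity scenarios A-K** — one-way perturbations of the reference
  case (exacerbation-free uplifts, mortality limits, discounting, cost and
  progression changes), reported as percent change of ΔQALY, ΔCost and the
  ICER relative to the reference run.

Both arms of every comparison share the same cohort and the same random
stream (common random numbers), which sharply reduces the variance of the
deltas.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import init_cohort
from .economics import IncrementalResult, compare_arms, compute_icer
from .engine import CohortOutcome, simulate_cohort
from .parameters import (
    ParameterSet,
    ParameterValidationError,
    SmokingStatus,
    Stage,
    build_mortality_table,
)

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "ABSTINENCE_RATES",
    "PROGRAMME_COSTS",
    "SENSITIVITY_SCENARIOS",
    "apply_scenario",
    "run_burden_of_smoking",
    "run_reference_case",
    "run_intervention_grid",
    "run_sensitivity_suite",
    "run_population_burden",
    "percent_change",
]

ABSTINENCE_RATES = {"100%": 1.0, "1/3": 1 / 3, "1/6": 1 / 6, "1/12": 1 / 12}
PROGRAMME_COSTS = (0.0, 100.0, 200.0, 500.0, 1000.0)


@dataclasses.dataclass
class ScenarioSpec:
    """One simulated arm-pair: intervention description plus run settings."""

    initial_abstinence_rate: float = 1.0
    programme_cost: float = 0.0
    turnover_enabled: bool = True
    stratum: str = "ALL"
    n: int = 100_000
    seed: int = 0
    modifier: str | None = None  # sensitivity-scenario letter or name

    def __post_init__(self):
        if not 0.0 <= self.initial_abstinence_rate <= 1.0:
            raise ValueError("initial_abstinence_rate must lie in [0, 1]")
        if self.programme_cost < 0:
            raise ValueError("programme_cost must be non-negative")


def _paired_arms(
    params: ParameterSet,
    stratum: str,
    n: int,
    seed: int,
    abstinence_rate: float,
    turnover: bool,
) -> tuple[CohortOutcome, CohortOutcome]:
    """Simulate comparator (all smokers) and intervention arms under CRN."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_switch, s_sim = ss.spawn(3)
    cohort = init_cohort(n, params, stratum=stratum, all_smokers=True, seed=np.random.default_rng(s_cohort))
    comparator = simulate_cohort(cohort, params, np.random.default_rng(s_sim), turnover=turnover)

    arm = cohort.copy()
    k = int(round(abstinence_rate * n))
    if k > 0:
        idx = np.random.default_rng(s_switch).choice(n, size=k, replace=False)
        arm.loc[idx, "smoking"] = int(SmokingStatus.EX_SMOKER)
    intervention = simulate_cohort(arm, params, np.random.default_rng(s_sim), turnover=turnover)
    return intervention, comparator


def run_burden_of_smoking(
    params: ParameterSet, stratum: str = "ALL", n: int = 100_000, seed: int = 0,
    keep_arms: bool = False,
):
    """Continuous smokers versus sustained quitters (turnover disabled).

    Returns the :class:`IncrementalResult` of the sustained-quitter arm over
    the continuous-smoker arm; with ``keep_arms`` the two
    :class:`CohortOutcome` objects are returned as well.
    """
    intervention, comparator = _paired_arms(
        params, stratum, n, seed, abstinence_rate=1.0, turnover=False
    )
    result = compare_arms(intervention, comparator, programme_cost=0.0)
    if keep_arms:
        return result, intervention, comparator
    return result


def run_reference_case(
    params: ParameterSet,
    stratum: str = "ALL",
    n: int = 100_000,
    seed: int = 0,
    abstinence_rate: float = 1.0,
    programme_cost: float = 0.0,
    keep_arms: bool = False,
):
    """Smoking-cessation intervention versus no intervention.

    A fraction ``abstinence_rate`` of the cohort is switched to ex-smoker at
    entry; background smoking turnover remains active in both arms.
    """
    intervention, comparator = _paired_arms(
        params, stratum, n, seed, abstinence_rate=abstinence_rate, turnover=True
    )
    result = compare_arms(intervention, comparator, programme_cost=programme_cost)
    if keep_arms:
        return result, intervention, comparator
    return result


def run_intervention_grid(
    params: ParameterSet,
    strata: Sequence[str] = ("ALL", "GOLD1", "GOLD2", "GOLD3", "GOLD4"),
    rates: dict[str, float] | None = None,
    costs: Sequence[float] = PROGRAMME_COSTS,
    n: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """The abstinence-rate x programme-cost cost-effectiveness grid.

    One paired simulation per (stratum, rate); each programme cost re-prices
    the same deltas (the ICER is affine in the cost with slope 1/ΔQALY).
    Identical seeds give a bit-identical grid.
    """
    rates = dict(ABSTINENCE_RATES) if rates is None else rates
    rows = []
    for stratum in strata:
        for label, rate in rates.items():
            res = run_reference_case(
                params, stratum=stratum, n=n, seed=seed, abstinence_rate=rate
            )
            row = {
                "stratum": stratum,
                "rate": label,
                "abstinence_rate": rate,
                "delta_cost": res.delta_cost,
                "delta_life_years": res.delta_life_years,
                "delta_qalys": res.delta_qalys,
            }
            for c in costs:
                row[f"icer_at_{c:g}"] = compute_icer(res.delta_cost, res.delta_qalys, c)
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# sensitivity scenarios A-K
# ----------------------------------------------------------------------


def _scale_exac_free(params: ParameterSet, factor: float, statuses) -> ParameterSet:
    """Raise the exacerbation-free probability multiplicatively, clamped at 1."""
    exac = params.exacerbation_prob.copy()
    for m in statuses:
        free = factor * (1.0 - exac[:, m])
        if np.any(free > 1.0):
            log.warning(
                "exacerbation-free proportion uplift clamped to 1 for some stages"
            )
        exac[:, m] = 1.0 - np.clip(free, 0.0, 1.0)
    return params.replace(exacerbation_prob=exac)


def _rebuild_mortality(params: ParameterSet, limit: str) -> ParameterSet:
    if not params.components or "copd_excess" not in params.components:
        raise ParameterValidationError(
            "mortality-limit scenarios need the mortality components the table was built from"
        )
    c = params.components
    death = build_mortality_table(
        c["all_cause"], c["copd_excess"][limit], c["smoking_hazard"],
        c["exacerbation_hazard"],
    )
    return params.replace(death_prob=death)


def _fit_progression_budget(params: ParameterSet) -> ParameterSet:
    """Shrink progression where progression + death would exceed 1, warning."""
    total = params.progression_prob[:, :, :, None] + params.death_prob
    if np.any(total > 1.0):
        log.warning("progression probabilities reduced to honour the one-cycle budget")
        room = np.clip(1.0 - params.death_prob.max(axis=3), 0.0, 1.0)
        prog = np.minimum(params.progression_prob, room)
        return params.replace(progression_prob=prog)
    return params


def _scale_death(params: ParameterSet, factor: float) -> ParameterSet:
    death = np.clip(factor * params.death_prob, 0.0, 1.0)
    return _fit_progression_budget(params.replace(death_prob=death))


def _scale_progression_rate(params: ParameterSet, factor: float) -> ParameterSet:
    prog = 1.0 - (1.0 - params.progression_prob) ** factor
    prog[Stage.GOLD4] = 0.0
    return _fit_progression_budget(params.replace(progression_prob=prog))


def _set_cost(params: ParameterSet, stage: Stage, value: float) -> ParameterSet:
    cost = params.annual_cost.copy()
    cost[stage] = value
    return params.replace(annual_cost=cost)


_EX = (SmokingStatus.EX_SMOKER,)
_BOTH = (SmokingStatus.SMOKER, SmokingStatus.EX_SMOKER)

#: Letter -> (descriptive name, transform of the reference parameter set).
SENSITIVITY_SCENARIOS: dict[str, tuple[str, Callable[[ParameterSet], ParameterSet]]] = {
    "A": ("ex_smoker_exac_free_plus_30pct", lambda p: _scale_exac_free(p, 1.30, _EX)),
    "B": ("excess_mortality_upper_limits", lambda p: _rebuild_mortality(p, "upper")),
    "C": ("death_probability_times_1_30", lambda p: _scale_death(p, 1.30)),
    "D": ("excess_mortality_lower_limits", lambda p: _rebuild_mortality(p, "lower")),
    "E": ("ex_smoker_exac_free_plus_15pct", lambda p: _scale_exac_free(p, 1.15, _EX)),
    "F": ("no_discounting", lambda p: p.replace(discount_rate=0.0)),
    "G": ("gold1_cost_zero", lambda p: _set_cost(p, Stage.GOLD1, 0.0)),
    "H": ("all_exac_free_plus_15pct", lambda p: _scale_exac_free(p, 1.15, _BOTH)),
    "I": ("discount_rate_5pct", lambda p: p.replace(discount_rate=0.05)),
    "J": ("all_costs_times_1_15", lambda p: p.replace(annual_cost=1.15 * p.annual_cost)),
    "K": ("progression_rate_times_1_30", lambda p: _scale_progression_rate(p, 1.30)),
}

_NAME_TO_LETTER = {name: letter for letter, (name, _) in SENSITIVITY_SCENARIOS.items()}


def apply_scenario(params: ParameterSet, which: str) -> ParameterSet:
    """Parameter set of sensitivity scenario ``which`` (letter or name)."""
    letter = _NAME_TO_LETTER.get(which, which)
    if letter not in SENSITIVITY_SCENARIOS:
        raise KeyError(f"unknown sensitivity scenario {which!r}")
    _, transform = SENSITIVITY_SCENARIOS[letter]
    return transform(params).validate()


def percent_change(scenario_value: float, reference_value: float) -> float:
    """Percent change of a scenario output versus the reference output."""
    return 100.0 * (scenario_value - reference_value) / reference_value


def run_sensitivity_suite(
    params: ParameterSet, n: int = 100_000, seed: int = 0,
    letters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run scenarios A-K and report outputs and percent changes vs reference.

    Every scenario reuses the reference run's cohort and random stream, so
    differences reflect the parameter perturbation alone.
    """
    reference = run_reference_case(params, n=n, seed=seed)
    rows = [
        {
            "scenario": "reference",
            "name": "reference_case",
            "delta_qalys": reference.delta_qalys,
            "delta_cost": reference.delta_cost,
            "icer": reference.icer,
            "pct_delta_qalys": 0.0,
            "pct_delta_cost": 0.0,
            "pct_icer": 0.0,
        }
    ]
    for letter in letters or SENSITIVITY_SCENARIOS:
        name, _ = SENSITIVITY_SCENARIOS[letter]
        res = run_reference_case(apply_scenario(params, letter), n=n, seed=seed)
        rows.append(
            {
                "scenario": letter,
                "name": name,
                "delta_qalys": res.delta_qalys,
                "delta_cost": res.delta_cost,
                "icer": res.icer,
                "pct_delta_qalys": percent_change(res.delta_qalys, reference.delta_qalys),
                "pct_delta_cost": percent_change(res.delta_cost, reference.delta_cost),
                "pct_icer": percent_change(res.icer, reference.icer),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class PopulationBurden:
    """Horizon-truncated national burden of continuous smoking."""

    total_cost: float  # GBP attributable to continuous smoking
    total_qalys_lost: float
    per_patient_cost: float
    per_patient_qalys_lost: float
    n_population: int
    horizon_years: int


def run_population_burden(
    params: ParameterSet,
    n_population: int = 1_400_000,
    horizon_years: int = 10,
    n: int = 100_000,
    seed: int = 0,
    discounted: bool = True,
) -> PopulationBurden:
    """Burden of continuous smoking in a national population of COPD smokers.

    Continuous smokers are compared to sustained quitters over the first
    ``horizon_years`` cycles only; per-patient excess cost and QALY loss are
    scaled to ``n_population`` patients.  Outcomes are discounted at the
    parameter set's rate unless ``discounted`` is False.
    """
    if horizon_years < 1:
        raise ValueError("horizon_years must be at least 1")
    if n_population < 0:
        raise ValueError("n_population must be non-negative")
    run_params = params if discounted else params.replace(discount_rate=0.0)
    _, quitters, smokers = run_burden_of_smoking(
        run_params, stratum="ALL", n=n, seed=seed, keep_arms=True
    )
    h = horizon_years

    def _head(outcome: CohortOutcome, col: str) -> float:
        return float(outcome.per_year[col].to_numpy()[:h].sum()) / outcome.n

    per_cost = _head(smokers, "cost") - _head(quitters, "cost")
    per_qaly = _head(quitters, "qalys") - _head(smokers, "qalys")
    return PopulationBurden(
        total_cost=per_cost * n_population,
        total_qalys_lost=per_qaly * n_population,
        per_patient_cost=per_cost,
        per_patient_qalys_lost=per_qaly,
        n_population=n_population,
        horizon_years=h,
    )
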