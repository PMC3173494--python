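"""Yearly-cycle simulation engine.

Each cycle a living patient is subjected, in this exact order, to

1. smoking turnover — a smoker quits with probability ``quit_prob``, an
   ex-smoker relapses with probability ``relapse_prob``;
2. an exacerbation draw from ``exacerbation_prob[stage, smoking]``;
3. a competing progression/death draw: the patient dies with
   ``death_prob[stage, band(age), smoking, exac]``, otherwise progresses to
   the next stage with ``progression_prob[stage, band(age), smoking]``
   (GOLD4 cannot progress), otherwise stays.

A patient alive at cycle start accrues the full year: one life-year, the
utility of the stage/exacerbation state occupied that cycle, and the stage's
annual cost.  Accruals of cycle ``t`` are discounted by ``(1 + r)^-t``
(cycle 0 undiscounted by default).  Age then increments; death or exceeding
``max_age`` removes the patient.

Two evaluation routes are provided: a Monte-Carlo patient-level simulation
(:func:`simulate_cohort`, vectorised over patients with one shared random
stream, so equal seeds give common random numbers across arms) and an exact
deterministic propagation of state-occupancy probabilities
(:func:`cohort_expectation`), which serves as the oracle the stochastic
route is validated against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import PatientState
from .parameters import (
    ENTRY_AGE_MIN,
    N_STAGES,
    ParameterSet,
    SmokingStatus,
    Stage,
)

__all__ = [
    "PatientOutcome",
    "CohortOutcome",
    "ExpectationResult",
    "discount_factor",
    "advance_cycle",
    "simulate_cohort",
    "cohort_expectation",
    "initial_distribution",
]


@dataclasses.dataclass
class PatientOutcome:
    """Discounted and undiscounted accruals of one simulated patient."""

    life_years: float
    qalys: float
    cost: float
    life_years_undiscounted: float
    qalys_undiscounted: float
    cost_undiscounted: float
    trace: list | None = None


@dataclasses.dataclass
class CohortOutcome:
    """Per-cohort summary of discounted outcomes.

    ``per_year`` holds cohort totals per cycle (columns ``cycle``, ``alive``,
    ``smokers``, ``cost``, ``life_years``, ``qalys``; monetary/QALY columns
    are discounted sums over patients), enabling horizon-truncated analyses.
    """

    n: int
    mean_cost: float
    sd_cost: float
    mean_life_years: float
    sd_life_years: float
    mean_qalys: float
    sd_qalys: float
    mean_cost_undiscounted: float
    mean_life_years_undiscounted: float
    mean_qalys_undiscounted: float
    per_year: pd.DataFrame | None = None
    per_patient: pd.DataFrame | None = None


@dataclasses.dataclass
class ExpectationResult:
    """Deterministic cohort expectation (per-patient units)."""

    cost: float
    life_years: float
    qalys: float
    cost_undiscounted: float
    life_years_undiscounted: float
    qalys_undiscounted: float
    per_year: pd.DataFrame
    stage_occupancy: np.ndarray  # (horizon + 1, 5): GOLD1..4 and DEAD


def discount_factor(cycle_index: int, rate: float, from_cycle_one: bool = False):
    """Discount multiplier ``(1 + rate)^-cycle_index``.

    ``cycle_index`` 0 is the cohort's first year and is undiscounted unless
    ``from_cycle_one`` shifts the schedule by one cycle.
    """
    idx = np.asarray(cycle_index)
    if np.any(idx < 0):
        raise ValueError(f"cycle_index must be non-negative, got {cycle_index}")
    if rate < 0:
        raise ValueError(f"discount rate must be non-negative, got {rate}")
    exponent = idx + 1 if from_cycle_one else idx
    out = (1.0 + rate) ** (-exponent.astype(float))
    return float(out) if np.isscalar(cycle_index) else out


def advance_cycle(
    state: PatientState, params: ParameterSet, rng: np.random.Generator,
    turnover: bool = True,
):
    """Advance one patient by one yearly cycle.

    Returns ``(new_state, (life_years, utility, cost))`` — the undiscounted
    accruals of the cycle.  Raises if called on a dead patient.  Three
    uniform draws are consumed per call in a fixed order (turnover,
    exacerbation, transition) so that trajectories are reproducible.
    """
    if not state.alive:
        raise ValueError("advance_cycle called on a dead patient")
    u_turn, u_exac, u_event = rng.random(3)

    smoking = state.smoking
    if turnover:
        if smoking == SmokingStatus.SMOKER and u_turn < params.quit_prob:
            smoking = SmokingStatus.EX_SMOKER
        elif smoking == SmokingStatus.EX_SMOKER and u_turn < params.relapse_prob:
            smoking = SmokingStatus.SMOKER

    stage = int(state.stage)
    exac = bool(u_exac < params.exacerbation_prob[stage, smoking])
    accrual = (1.0, float(params.utility[stage, int(exac)]),
               float(params.annual_cost[stage]))

    band = int(params.band_index(state.age))
    p_die = float(params.death_prob[stage, band, smoking, int(exac)])
    p_prog = float(params.progression_prob[stage, band, smoking]) * (1.0 - p_die)

    new_stage = stage
    alive = True
    if u_event < p_die:
        alive = False
    elif u_event < p_die + p_prog:
        new_stage = stage + 1  # never reached for GOLD4: its progression is 0
    age = state.age + 1
    if age > params.max_age:
        alive = False
    new_state = PatientState(
        age=age,
        stage=Stage(new_stage) if alive else Stage.DEAD,
        smoking=SmokingStatus(smoking),
        exacerbated=exac,
        alive=alive,
    )
    return new_state, accrual


def simulate_cohort(
    cohort: pd.DataFrame,
    params: ParameterSet,
    seed: int | np.random.Generator,
    turnover: bool = True,
    horizon: int | None = None,
    collect_per_year: bool = True,
    keep_patient_outcomes: bool = False,
    collect_traces: bool = False,
) -> CohortOutcome:
    """Monte-Carlo simulation of a cohort until death or ``max_age``.

    The random stream consumes exactly ``3 n`` uniforms per cycle regardless
    of how many patients remain alive, so two arms simulated with the same
    seed and cohort size share event draws cycle for cycle (common random
    numbers).

    Parameters
    ----------
    cohort
        Frame from :func:`copdsim.cohort.init_cohort`; all patients alive.
    seed
        Integer seed or generator; results are deterministic given
        ``(cohort, seed)``.
    turnover
        Disable to freeze smoking status (continuous smokers / sustained
        quitters).
    horizon
        Optional cap on the number of cycles simulated.
    collect_traces
        Record the per-cycle stage matrix (small cohorts only); returned in
        ``per_patient.attrs["stage_trace"]``.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot simulate an empty cohort")
    if not cohort["alive"].all():
        raise ValueError("all patients must be alive at cohort entry")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    age = cohort["age"].to_numpy(dtype=np.int64).copy()
    stage = cohort["stage"].to_numpy(dtype=np.int64).copy()
    smoking = cohort["smoking"].to_numpy(dtype=np.int64).copy()
    alive = np.ones(n, dtype=bool)

    disc = np.zeros((3, n))  # rows: cost, life-years, qalys
    undisc = np.zeros((3, n))
    per_year_rows = []
    traces = [stage.copy()] if collect_traces else None

    t = 0
    max_cycles = params.max_age - ENTRY_AGE_MIN + 1
    while alive.any() and t < max_cycles and (horizon is None or t < horizon):
        u = rng.random((3, n))
        if turnover:
            quits = alive & (smoking == SmokingStatus.SMOKER) & (u[0] < params.quit_prob)
            relapses = (
                alive & (smoking == SmokingStatus.EX_SMOKER) & (u[0] < params.relapse_prob)
            )
            smoking[quits] = SmokingStatus.EX_SMOKER
            smoking[relapses] = SmokingStatus.SMOKER

        exac = u[1] < params.exacerbation_prob[stage, smoking]

        d = discount_factor(t, params.discount_rate, params.discount_from_cycle_one)
        util = params.utility[stage, exac.astype(np.int64)]
        cost = params.annual_cost[stage]
        a = alive.astype(float)
        cycle = np.vstack([cost * a, a, util * a])
        disc += d * cycle
        undisc += cycle
        if collect_per_year:
            per_year_rows.append(
                (
                    t,
                    int(alive.sum()),
                    int((alive & (smoking == SmokingStatus.SMOKER)).sum()),
                    d * cycle[0].sum(),
                    d * cycle[1].sum(),
                    d * cycle[2].sum(),
                )
            )

        band = params.band_index(age)
        p_die = params.death_prob[stage, band, smoking, exac.astype(np.int64)]
        p_prog = params.progression_prob[stage, band, smoking] * (1.0 - p_die)
        dies = alive & (u[2] < p_die)
        progresses = alive & ~dies & (u[2] < p_die + p_prog)
        stage[progresses] += 1
        alive &= ~dies
        age[alive] += 1
        alive &= age <= params.max_age
        if collect_traces:
            traces.append(np.where(alive, stage, Stage.DEAD).copy())
        t += 1

    def _summ(row):
        return float(row.mean()), float(row.std(ddof=1)) if n > 1 else 0.0

    mean_cost, sd_cost = _summ(disc[0])
    mean_ly, sd_ly = _summ(disc[1])
    mean_q, sd_q = _summ(disc[2])
    per_year = (
        pd.DataFrame(
            per_year_rows,
            columns=["cycle", "alive", "smokers", "cost", "life_years", "qalys"],
        )
        if collect_per_year
        else None
    )
    per_patient = None
    if keep_patient_outcomes or collect_traces:
        per_patient = pd.DataFrame(
            {
                "id": cohort["id"].to_numpy(),
                "cost": disc[0],
                "life_years": disc[1],
                "qalys": disc[2],
            }
        )
        if collect_traces:
            per_patient.attrs["stage_trace"] = np.array(traces)
    return CohortOutcome(
        n=n,
        mean_cost=mean_cost,
        sd_cost=sd_cost,
        mean_life_years=mean_ly,
        sd_life_years=sd_ly,
        mean_qalys=mean_q,
        sd_qalys=sd_q,
        mean_cost_undiscounted=float(undisc[0].mean()),
        mean_life_years_undiscounted=float(undisc[1].mean()),
        mean_qalys_undiscounted=float(undisc[2].mean()),
        per_year=per_year,
        per_patient=per_patient,
    )


def initial_distribution(
    params: ParameterSet,
    stratum: str = "ALL",
    smoker_fraction: float = 1.0,
) -> np.ndarray:
    """Exact entry-state distribution over (stage, age, smoking).

    Returns an array ``(4, max_age - 40 + 1, 2)`` summing to 1, matching what
    :func:`copdsim.cohort.init_cohort` samples from: stages per the severity
    distribution (or a point mass for a named stratum), ages uniform within
    each 10-year class, and the given smoker/ex-smoker split.
    """
    if not 0.0 <= smoker_fraction <= 1.0:
        raise ValueError("smoker_fraction must lie in [0, 1]")
    n_ages = params.max_age - ENTRY_AGE_MIN + 1
    dist = np.zeros((N_STAGES, n_ages, 2))
    if stratum == "ALL":
        stage_w = params.severity_distribution
    else:
        stage_w = np.zeros(N_STAGES)
        stage_w[Stage[stratum].value] = 1.0
    smoking_w = np.array([smoker_fraction, 1.0 - smoker_fraction])
    from .parameters import AGE_CLASS_WIDTH  # local import avoids cycle at module load

    for s in range(N_STAGES):
        for c, lower in enumerate(params.age_class_lowers):
            w = stage_w[s] * params.age_distribution[s, c] / AGE_CLASS_WIDTH
            i0 = int(lower) - ENTRY_AGE_MIN
            dist[s, i0 : i0 + AGE_CLASS_WIDTH, :] += w * smoking_w
    return dist


def cohort_expectation(
    params: ParameterSet,
    initial: np.ndarray,
    horizon: int | None = None,
    turnover: bool = True,
) -> ExpectationResult:
    """Exact forward propagation of state-occupancy probabilities.

    Applies the same cycle rules as the Monte-Carlo engine to the occupancy
    array ``(stage, age, smoking)``, taking expectations over the
    exacerbation mixture within each state.  Because the cycle's event
    probabilities are linear in the exacerbation indicator, the expectation
    is exact, and this routine is the deterministic oracle for
    :func:`simulate_cohort`.

    ``horizon`` defaults to the number of cycles needed for the whole cohort
    to die out (``max_age - 40 + 1``).  Occupancy conservation (living +
    dead mass = 1) is checked to 1e-9 every cycle.
    """
    n_ages = params.max_age - ENTRY_AGE_MIN + 1
    P = np.asarray(initial, dtype=float).copy()
    if P.shape != (N_STAGES, n_ages, 2):
        raise ValueError(
            f"initial distribution must have shape {(N_STAGES, n_ages, 2)}, got {P.shape}"
        )
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial distribution sums to {P.sum()}, not 1")
    if horizon is None:
        horizon = n_ages
    if horizon < 1:
        raise ValueError("horizon must be at least 1 cycle")

    bidx = params.band_index(np.arange(ENTRY_AGE_MIN, params.max_age + 1))
    pe = params.exacerbation_prob  # (S, M)
    u_mix = (1 - pe) * params.utility[:, :1] + pe * params.utility[:, 1:]  # (S, M)
    death = params.death_prob[:, bidx, :, :]  # (S, A, M, E)
    prog = params.progression_prob[:, bidx, :]  # (S, A, M)
    pd_avg = (1 - pe[:, None, :]) * death[..., 0] + pe[:, None, :] * death[..., 1]
    pp_eff = prog * (1 - pd_avg)

    dead = 0.0
    acc_d = np.zeros(3)  # cost, life-years, qalys (discounted)
    acc_u = np.zeros(3)
    rows = []
    occupancy = np.empty((horizon + 1, N_STAGES + 1))
    occupancy[0, :N_STAGES] = P.sum(axis=(1, 2))
    occupancy[0, N_STAGES] = dead

    q, r = params.quit_prob, params.relapse_prob
    for t in range(horizon):
        if turnover:
            smokers = P[:, :, 0].copy()
            P[:, :, 0] = smokers * (1 - q) + P[:, :, 1] * r
            P[:, :, 1] = P[:, :, 1] * (1 - r) + smokers * q

        d = discount_factor(t, params.discount_rate, params.discount_from_cycle_one)
        alive_mass = P.sum()
        cost = float((P.sum(axis=1) * params.annual_cost[:, None]).sum())
        qaly = float((P.sum(axis=1) * u_mix).sum())
        cycle = np.array([cost, alive_mass, qaly])
        acc_d += d * cycle
        acc_u += cycle
        rows.append((t, alive_mass, float(P[:, :, 0].sum()), *(d * cycle)))

        dead += float((P * pd_avg).sum())
        stay = P * (1 - pd_avg - pp_eff)
        flow = P * pp_eff
        dead += float(stay[:, -1, :].sum() + flow[:, -1, :].sum())  # age out
        P = np.zeros_like(P)
        P[:, 1:, :] = stay[:, :-1, :]
        P[1:, 1:, :] += flow[:-1, :-1, :]

        occupancy[t + 1, :N_STAGES] = P.sum(axis=(1, 2))
        occupancy[t + 1, N_STAGES] = dead
        total = P.sum() + dead
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"occupancy mass {total} drifted from 1 at cycle {t}")

    per_year = pd.DataFrame(
        rows, columns=["cycle", "alive", "smokers", "cost", "life_years", "qalys"]
    )
    return ExpectationResult(
        cost=float(acc_d[0]),
        life_years=float(acc_d[1]),
        qalys=float(acc_d[2]),
        cost_undiscounted=float(acc_u[0]),
        life_years_undiscounted=float(acc_u[1]),
        qalys_undiscounted=float(acc_u[2]),
        per_year=per_year,
        stage_occupancy=occupancy,
    )
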