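"""Initial cohort construction.

A simulated patient enters with a COPD severity stage, an integer entry age
between 40 and 89 years, and a smoking status.  Stages are drawn from the
severity distribution (or fixed, for single-stage strata), entry ages from
the per-stage distribution over 10-year age classes (uniform within each
class), and every patient starts alive and exacerbation-free.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .parameters import (
    AGE_CLASS_WIDTH,
    N_STAGES,
    STAGE_NAMES,
    ParameterSet,
    SmokingStatus,
    Stage,
)

__all__ = ["PatientState", "STRATA", "init_cohort", "write_cohort", "read_cohort"]

STRATA = ("ALL",) + STAGE_NAMES

_COLUMNS = ["id", "age", "stage", "smoking", "exacerbated", "alive"]


@dataclasses.dataclass
class PatientState:
    """One simulated patient's current state."""

    age: int
    stage: Stage
    smoking: SmokingStatus
    exacerbated: bool = False
    alive: bool = True

    def __post_init__(self):
        if (self.stage == Stage.DEAD) != (not self.alive):
            raise ValueError("stage is DEAD if and only if the patient is not alive")


def _quota_counts(n: int, probs: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n draws to len(probs) cells."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def init_cohort(
    n: int,
    params: ParameterSet,
    stratum: str = "ALL",
    all_smokers: bool = True,
    seed: int | np.random.Generator = 0,
    exact_quota: bool = False,
) -> pd.DataFrame:
    """Sample an initial cohort of ``n`` patients.

    Parameters
    ----------
    n
        Cohort size (>= 1).
    params
        Model parameters supplying the severity and entry-age distributions.
    stratum
        ``"ALL"`` draws stages from the severity distribution; a stage name
        (``"GOLD1"`` .. ``"GOLD4"``) fixes every patient to that stage.
    all_smokers
        If True (the study's entry condition) every patient enters as a
        smoker; otherwise every patient enters as an ex-smoker.  Intervention
        scenarios flip a fraction of smokers after initialisation.
    seed
        Integer seed or a ready :class:`numpy.random.Generator`; identical
        seeds give identical cohorts.
    exact_quota
        Allocate stage counts by largest remainder instead of independent
        draws (variance reduction for tests); ages are still sampled.

    Returns
    -------
    pandas.DataFrame
        Columns ``id, age, stage, smoking, exacerbated, alive`` with integer
        stage/smoking codes per :class:`~copdsim.parameters.Stage` and
        :class:`~copdsim.parameters.SmokingStatus`.
    """
    if n < 1:
        raise ValueError(f"cohort size must be positive, got {n}")
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if stratum == "ALL":
        if exact_quota:
            counts = _quota_counts(n, params.severity_distribution)
            stage = rng.permutation(np.repeat(np.arange(N_STAGES), counts))
        else:
            stage = rng.choice(N_STAGES, size=n, p=params.severity_distribution)
    else:
        stage = np.full(n, Stage[stratum].value, dtype=np.int64)

    n_classes = len(params.age_class_lowers)
    age = np.empty(n, dtype=np.int64)
    for s in range(N_STAGES):
        mask = stage == s
        k = int(mask.sum())
        if k == 0:
            continue
        cls = rng.choice(n_classes, size=k, p=params.age_distribution[s])
        age[mask] = params.age_class_lowers[cls] + rng.integers(
            0, AGE_CLASS_WIDTH, size=k
        )

    smoking_code = SmokingStatus.SMOKER if all_smokers else SmokingStatus.EX_SMOKER
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "stage": stage.astype(np.int64),
            "smoking": np.full(n, int(smoking_code), dtype=np.int64),
            "exacerbated": np.zeros(n, dtype=bool),
            "alive": np.ones(n, dtype=bool),
        }
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Dump a cohort as tab-delimited text (one row per patient)."""
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    """Restore a cohort written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks columns: {missing}")
    return df[_COLUMNS].astype(
        {"id": np.int64, "age": np.int64, "stage": np.int64,
         "smoking": np.int64, "exacerbated": bool, "alive": bool}
    )
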