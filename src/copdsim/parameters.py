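"""Model parameters for the COPD smoking-cessation microsimulation.

The model follows chronic obstructive pulmonary disease (COPD) patients
through yearly cycles in which smoking status may change, an exacerbation may
occur, and the patient may progress to the next GOLD severity stage or die.
This module holds every rate, probability, utility and cost the simulation
consumes, validates them, reads/writes the YAML configuration format, and
constructs the derived stage-progression and mortality tables from documented
component inputs.

Hazard composition
------------------
Published sources give annual *probabilities* while severity, smoking status
and exacerbations act as *relative hazards*.  The builders therefore convert
probabilities to rates (``rate = -ln(1 - p)``), compose hazards
multiplicatively on the rate scale, and convert back
(``p = 1 - exp(-h * rate)``).  This keeps every derived probability inside
[0, 1] for any positive hazard.
"""

from __future__ import annotations

import dataclasses
import enum
import functools
import importlib.resources
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "SmokingStatus",
    "ParameterSet",
    "ParameterError",
    "ParameterParseError",
    "ParameterValidationError",
    "prob_to_rate",
    "rate_to_prob",
    "build_progression_table",
    "build_mortality_table",
    "load_parameters",
    "read_parameters",
    "write_parameters",
    "default_parameters",
]

N_STAGES = 4
ENTRY_AGE_MIN = 40
ENTRY_AGE_MAX = 89
AGE_CLASS_WIDTH = 10


class Stage(enum.IntEnum):
    """Ordered COPD severity states; DEAD is absorbing."""

    GOLD1 = 0
    GOLD2 = 1
    GOLD3 = 2
    GOLD4 = 3
    DEAD = 4


LIVING_STAGES = (Stage.GOLD1, Stage.GOLD2, Stage.GOLD3, Stage.GOLD4)
STAGE_NAMES = tuple(s.name for s in LIVING_STAGES)


class SmokingStatus(enum.IntEnum):
    SMOKER = 0
    EX_SMOKER = 1


class ParameterError(ValueError):
    """Base class for parameter-handling failures."""


class ParameterParseError(ParameterError):
    """The configuration document could not be parsed or lacks required keys."""


class ParameterValidationError(ParameterError):
    """A parameter value violates a model invariant."""


def prob_to_rate(p):
    """Annual probability -> annual rate, ``-ln(1 - p)``."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return -np.log1p(-p)


def rate_to_prob(r):
    """Annual rate -> annual probability, ``1 - exp(-r)``."""
    return -np.expm1(-np.asarray(r, dtype=float))


def build_progression_table(
    baseline_prob: np.ndarray, smoking_modifier: Sequence[float]
) -> np.ndarray:
    """Build the stage-progression probability table.

    Parameters
    ----------
    baseline_prob
        Array ``(n_progressing_stages, n_bands)`` of annual probabilities of
        moving to the next stage for the reference smoking status.  Three
        rows (GOLD1-3) are expected; a fourth all-zero row for GOLD4 (which
        cannot progress) is appended if absent.
    smoking_modifier
        Length-2 sequence of relative progression factors, indexed by
        :class:`SmokingStatus` (smoker first).  The ex-smoker modifier must
        not exceed the smoker modifier.

    Returns
    -------
    numpy.ndarray
        Table ``(4, n_bands, 2)`` of probabilities
        ``1 - exp(-modifier * rate(baseline))``.
    """
    baseline = np.asarray(baseline_prob, dtype=float)
    mods = np.asarray(smoking_modifier, dtype=float)
    if mods.shape != (2,):
        raise ParameterValidationError(
            f"smoking_modifier must have one entry per smoking status, got {mods!r}"
        )
    if np.any(mods <= 0):
        raise ParameterValidationError(
            f"smoking_modifier entries must be positive, got {mods!r}"
        )
    if mods[SmokingStatus.EX_SMOKER] > mods[SmokingStatus.SMOKER]:
        raise ParameterValidationError(
            "ex-smoker progression modifier exceeds the smoker modifier: "
            f"{mods[1]} > {mods[0]}"
        )
    if baseline.ndim != 2:
        raise ParameterValidationError("baseline_prob must be 2-D (stage x age band)")
    if baseline.shape[0] == N_STAGES - 1:
        baseline = np.vstack([baseline, np.zeros(baseline.shape[1])])
    if baseline.shape[0] != N_STAGES:
        raise ParameterValidationError(
            f"baseline_prob must have 3 or 4 stage rows, got {baseline.shape[0]}"
        )
    if np.any((baseline < 0) | (baseline > 1)):
        raise ParameterValidationError("baseline progression probabilities outside [0, 1]")
    if np.any(baseline[Stage.GOLD4] != 0):
        raise ParameterValidationError("GOLD4 cannot progress; its baseline row must be 0")
    if np.any(baseline == 1):
        log.warning("baseline progression probability of 1 clamped to 1 in output")
    rate = prob_to_rate(baseline)  # (4, B), inf where baseline == 1
    out = rate_to_prob(rate[:, :, None] * mods[None, None, :])
    return np.nan_to_num(out, nan=1.0, posinf=1.0)


def build_mortality_table(
    all_cause_prob: np.ndarray,
    copd_excess: Sequence[float],
    smoking_hazard: Sequence[float],
    exac_hazard: Sequence[float],
) -> np.ndarray:
    """Build the death-probability table from multiplicative relative hazards.

    ``death[stage, band, status, exac] =
    1 - exp(-excess[stage] * smoking[status] * exac[flag] * rate(all_cause[band]))``

    ``all_cause_prob`` is the general-population annual death probability per
    age band (values in [0, 1)); the three hazard vectors are relative to it
    and must be non-negative.
    """
    ac = np.asarray(all_cause_prob, dtype=float)
    ce = np.asarray(copd_excess, dtype=float)
    sh = np.asarray(smoking_hazard, dtype=float)
    eh = np.asarray(exac_hazard, dtype=float)
    if np.any((ac < 0) | (ac >= 1)):
        raise ParameterValidationError("all_cause_prob entries must lie in [0, 1)")
    for name, arr, shape in (
        ("copd_excess", ce, (N_STAGES,)),
        ("smoking_hazard", sh, (2,)),
        ("exac_hazard", eh, (2,)),
    ):
        if arr.shape != shape:
            raise ParameterValidationError(f"{name} must have shape {shape}, got {arr.shape}")
        if np.any(arr < 0):
            raise ParameterValidationError(f"{name} entries must be non-negative, got {arr!r}")
    rate = prob_to_rate(ac)  # (B,)
    h = ce[:, None, None, None] * sh[None, None, :, None] * eh[None, None, None, :]
    return rate_to_prob(h * rate[None, :, None, None])


@dataclasses.dataclass
class ParameterSet:
    """Everything the simulation consumes, in array form.

    Array axes follow a fixed convention: stage (GOLD1..GOLD4), age band,
    smoking status (smoker, ex-smoker), exacerbation flag (stable,
    exacerbated).

    Attributes
    ----------
    severity_distribution : (4,) fractions of the cohort entering each stage.
    age_class_lowers : (C,) lower bounds of the 10-year entry-age classes.
    age_distribution : (4, C) per-stage weights over entry-age classes.
    quit_prob, relapse_prob : annual smoking-turnover probabilities.
    exacerbation_prob : (4, 2) probability of >=1 exacerbation per year, by
        stage and smoking status (both columns equal in the reference case).
    progression_prob : (4, B, 2) annual probability of moving to the next
        stage; the GOLD4 row is zero.
    death_prob : (4, B, 2, 2) annual probability of death.
    utility : (4, 2) QALY weight per year, by stage and exacerbation flag.
    annual_cost : (4,) disease cost in GBP per patient-year.
    discount_rate : annual discount fraction applied to costs and QALYs.
    max_age : hard stop of the simulation, in years.
    age_band_lowers : (B,) lower bounds of the table age bands; the last band
        is open-ended and is reused for any older age.
    discount_from_cycle_one : if True the first cycle is already discounted;
        the default leaves cycle 0 undiscounted.
    components : the raw builder inputs the tables were derived from (needed
        by sensitivity scenarios that rebuild the mortality table), or None
        when tables were supplied directly.
    """

    severity_distribution: np.ndarray
    age_class_lowers: np.ndarray
    age_distribution: np.ndarray
    quit_prob: float
    relapse_prob: float
    exacerbation_prob: np.ndarray
    progression_prob: np.ndarray
    death_prob: np.ndarray
    utility: np.ndarray
    annual_cost: np.ndarray
    discount_rate: float
    max_age: int
    age_band_lowers: np.ndarray
    discount_from_cycle_one: bool = False
    components: dict | None = None
    _warned_band_overflow: bool = dataclasses.field(
        default=False, repr=False, compare=False
    )

    # -- lookups ---------------------------------------------------------

    @property
    def n_bands(self) -> int:
        return len(self.age_band_lowers)

    def band_index(self, ages) -> np.ndarray:
        """Map integer ages to table band indices.

        Ages above the nominal coverage of the last band reuse the last band;
        this is logged once per parameter set.
        """
        ages = np.asarray(ages)
        idx = np.searchsorted(self.age_band_lowers, ages, side="right") - 1
        last_upper = self.age_band_lowers[-1] + AGE_CLASS_WIDTH - 1
        if not self._warned_band_overflow and np.any(ages > last_upper):
            log.info(
                "ages above %d reuse the last age band of the tables", last_upper
            )
            object.__setattr__(self, "_warned_band_overflow", True)
        return np.clip(idx, 0, self.n_bands - 1)

    # -- modification helpers -------------------------------------------

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields replaced (arrays are copied)."""
        base = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if not f.name.startswith("_")
        }
        for k, v in base.items():
            if isinstance(v, np.ndarray):
                base[k] = v.copy()
        base.update(changes)
        return ParameterSet(**base)

    # -- validation ------------------------------------------------------

    def validate(self) -> "ParameterSet":
        """Check every invariant; raise :class:`ParameterValidationError`."""

        def _bad(field, value, why):
            raise ParameterValidationError(f"{field} = {value!r}: {why}")

        sd = self.severity_distribution
        if sd.shape != (N_STAGES,):
            _bad("severity_distribution", sd, "must have one entry per living stage")
        if np.any((sd < 0) | (sd > 1)):
            _bad("severity_distribution", sd, "entries must lie in [0, 1]")
        if abs(sd.sum() - 1.0) > 1e-9:
            _bad("severity_distribution", sd.sum(), "must sum to 1 within 1e-9")
        if self.age_distribution.shape != (N_STAGES, len(self.age_class_lowers)):
            _bad("age_distribution", self.age_distribution.shape,
                 "must be stage x age-class")
        if np.any(self.age_distribution < 0) or np.any(
            np.abs(self.age_distribution.sum(axis=1) - 1.0) > 1e-9
        ):
            _bad("age_distribution", self.age_distribution,
                 "rows must be distributions summing to 1")
        for name in ("quit_prob", "relapse_prob", "discount_rate"):
            v = getattr(self, name)
            hi = 1.0 if name != "discount_rate" else math.inf
            if not (0.0 <= v <= hi):
                _bad(name, v, "must be a probability in [0, 1]"
                     if name != "discount_rate" else "must be non-negative")
        B = self.n_bands
        shapes = {
            "exacerbation_prob": (self.exacerbation_prob, (N_STAGES, 2)),
            "progression_prob": (self.progression_prob, (N_STAGES, B, 2)),
            "death_prob": (self.death_prob, (N_STAGES, B, 2, 2)),
            "utility": (self.utility, (N_STAGES, 2)),
        }
        for name, (arr, shape) in shapes.items():
            if arr.shape != shape:
                _bad(name, arr.shape, f"must have shape {shape}")
            if np.any((arr < 0) | (arr > 1)):
                _bad(name, arr, "entries must lie in [0, 1]")
        if np.any(self.progression_prob[Stage.GOLD4] != 0):
            _bad("progression_prob", self.progression_prob[Stage.GOLD4],
                 "GOLD4 cannot progress")
        # competing-event budget: progression + death must fit in one cycle
        total = self.progression_prob[:, :, :, None] + self.death_prob
        if np.any(total > 1 + 1e-12):
            idx = np.unravel_index(np.argmax(total), total.shape)
            _bad("progression_prob + death_prob", float(total[idx]),
                 f"exceeds 1 at (stage, band, smoking, exac) = {idx}")
        if np.any(self.annual_cost < 0):
            _bad("annual_cost", self.annual_cost, "costs must be non-negative")
        if self.max_age < ENTRY_AGE_MAX:
            _bad("max_age", self.max_age, f"must be at least {ENTRY_AGE_MAX}")
        return self


# ----------------------------------------------------------------------
# configuration I/O
# ----------------------------------------------------------------------

_REQUIRED_KEYS = (
    "severity_distribution",
    "quit_prob",
    "relapse_prob",
    "exacerbation_prob",
    "utility",
    "annual_cost",
)


def _stage_map_to_array(value, key: str) -> np.ndarray:
    if isinstance(value, Mapping):
        try:
            return np.array([float(value[name]) for name in STAGE_NAMES])
        except KeyError as e:
            raise ParameterParseError(f"{key} is missing stage {e.args[0]}") from e
    return np.asarray(value, dtype=float)


@functools.lru_cache(maxsize=1)
def _default_document() -> dict:
    text = (
        importlib.resources.files("copdsim.data")
        .joinpath("default_parameters.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def load_parameters(config_text: str) -> ParameterSet:
    """Parse a YAML parameter document into a validated :class:`ParameterSet`.

    Required keys: ``severity_distribution``, ``quit_prob``, ``relapse_prob``,
    ``exacerbation_prob``, ``utility``, ``annual_cost``.  Optional keys
    (``discount_rate``, ``max_age``, age and table blocks) fall back to the
    bundled defaults with a logged warning.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ParameterParseError(f"malformed parameter document{line}: {e}") from e
    if not isinstance(doc, Mapping):
        raise ParameterParseError("parameter document must be a mapping")
    missing = [k for k in _REQUIRED_KEYS if k not in doc]
    if missing:
        raise ParameterParseError(f"missing required keys: {', '.join(missing)}")
    return _parameters_from_document(dict(doc))


def _parameters_from_document(doc: dict) -> ParameterSet:
    defaults = _default_document()

    def _opt(key):
        if key in doc:
            return doc[key]
        log.warning("parameter key %r missing; using bundled default", key)
        return defaults[key]

    severity = _stage_map_to_array(doc["severity_distribution"], "severity_distribution")

    age_classes = np.asarray(_opt("age_classes"), dtype=int)
    age_dist_doc = _opt("age_distribution")
    age_dist = np.array(
        [np.asarray(age_dist_doc[name], dtype=float) for name in STAGE_NAMES]
    )

    exac_doc = doc["exacerbation_prob"]
    exac = np.empty((N_STAGES, 2))
    for i, name in enumerate(STAGE_NAMES):
        v = exac_doc[name]
        if isinstance(v, Mapping):
            exac[i] = [float(v["SMOKER"]), float(v["EX_SMOKER"])]
        else:
            exac[i] = float(v)

    util_doc = doc["utility"]
    utility = np.column_stack(
        [
            _stage_map_to_array(util_doc["stable"], "utility.stable"),
            _stage_map_to_array(util_doc["exacerbated"], "utility.exacerbated"),
        ]
    )
    cost = _stage_map_to_array(doc["annual_cost"], "annual_cost")

    bands = np.asarray(_opt("age_bands"), dtype=int)
    components: dict = {}

    if "progression_table" in doc:
        prog = np.asarray(doc["progression_table"], dtype=float)
    else:
        pc = _opt("progression_components")
        baseline = np.array(
            [np.asarray(pc["baseline"][name], dtype=float) for name in STAGE_NAMES[:3]]
        )
        mod = np.array(
            [float(pc["smoking_modifier"]["SMOKER"]),
             float(pc["smoking_modifier"]["EX_SMOKER"])]
        )
        prog = build_progression_table(baseline, mod)
        components["progression_baseline"] = np.vstack(
            [baseline, np.zeros(baseline.shape[1])]
        )
        components["progression_smoking_modifier"] = mod

    if "mortality_table" in doc:
        death = np.asarray(doc["mortality_table"], dtype=float)
    else:
        mc = _opt("mortality_components")
        all_cause = np.asarray(mc["all_cause"], dtype=float)
        excess = {
            k: _stage_map_to_array(mc["copd_excess"][k], f"copd_excess.{k}")
            for k in ("central", "upper", "lower")
        }
        sh = np.array(
            [float(mc["smoking_hazard"]["SMOKER"]),
             float(mc["smoking_hazard"]["EX_SMOKER"])]
        )
        eh = np.array(
            [float(mc["exacerbation_hazard"]["stable"]),
             float(mc["exacerbation_hazard"]["exacerbated"])]
        )
        death = build_mortality_table(all_cause, excess["central"], sh, eh)
        components.update(
            all_cause=all_cause,
            copd_excess=excess,
            smoking_hazard=sh,
            exacerbation_hazard=eh,
        )

    ps = ParameterSet(
        severity_distribution=severity,
        age_class_lowers=age_classes,
        age_distribution=age_dist,
        quit_prob=float(doc["quit_prob"]),
        relapse_prob=float(doc["relapse_prob"]),
        exacerbation_prob=exac,
        progression_prob=prog,
        death_prob=death,
        utility=utility,
        annual_cost=cost,
        discount_rate=float(_opt("discount_rate")),
        max_age=int(_opt("max_age")),
        age_band_lowers=bands,
        discount_from_cycle_one=bool(doc.get("discount_from_cycle_one", False)),
        components=components or None,
    )
    return ps.validate()


def read_parameters(path) -> ParameterSet:
    """Load a parameter file, or the bundled defaults for path ``"default"``."""
    if str(path) == "default":
        return default_parameters()
    with open(path) as fh:
        return load_parameters(fh.read())


def write_parameters(params: ParameterSet) -> str:
    """Serialise a :class:`ParameterSet` back to the YAML schema.

    Inverse of :func:`load_parameters` up to key ordering: when the tables
    were built from components, the components (not the derived tables) are
    written back.
    """

    def _stage_map(arr):
        return {name: float(arr[i]) for i, name in enumerate(STAGE_NAMES)}

    doc: dict = {"severity_distribution": _stage_map(params.severity_distribution)}
    doc["age_classes"] = [int(x) for x in params.age_class_lowers]
    doc["age_distribution"] = {
        name: [float(x) for x in params.age_distribution[i]]
        for i, name in enumerate(STAGE_NAMES)
    }
    doc["quit_prob"] = float(params.quit_prob)
    doc["relapse_prob"] = float(params.relapse_prob)
    exac = params.exacerbation_prob
    doc["exacerbation_prob"] = {
        name: (
            float(exac[i, 0])
            if exac[i, 0] == exac[i, 1]
            else {"SMOKER": float(exac[i, 0]), "EX_SMOKER": float(exac[i, 1])}
        )
        for i, name in enumerate(STAGE_NAMES)
    }
    doc["utility"] = {
        "stable": _stage_map(params.utility[:, 0]),
        "exacerbated": _stage_map(params.utility[:, 1]),
    }
    doc["annual_cost"] = _stage_map(params.annual_cost)
    doc["discount_rate"] = float(params.discount_rate)
    doc["max_age"] = int(params.max_age)
    doc["discount_from_cycle_one"] = bool(params.discount_from_cycle_one)
    doc["age_bands"] = [int(x) for x in params.age_band_lowers]
    c = params.components or {}
    if "all_cause" in c:
        doc["mortality_components"] = {
            "all_cause": [float(x) for x in c["all_cause"]],
            "copd_excess": {k: _stage_map(v) for k, v in c["copd_excess"].items()},
            "smoking_hazard": {
                "SMOKER": float(c["smoking_hazard"][0]),
                "EX_SMOKER": float(c["smoking_hazard"][1]),
            },
            "exacerbation_hazard": {
                "stable": float(c["exacerbation_hazard"][0]),
                "exacerbated": float(c["exacerbation_hazard"][1]),
            },
        }
    else:
        doc["mortality_table"] = params.death_prob.tolist()
    if "progression_baseline" in c:
        doc["progression_components"] = {
            "baseline": {
                name: [float(x) for x in c["progression_baseline"][i]]
                for i, name in enumerate(STAGE_NAMES[:3])
            },
            "smoking_modifier": {
                "SMOKER": float(c["progression_smoking_modifier"][0]),
                "EX_SMOKER": float(c["progression_smoking_modifier"][1]),
            },
        }
    else:
        doc["progression_table"] = params.progression_prob.tolist()
    return yaml.safe_dump(doc, sort_keys=False)


def default_parameters() -> ParameterSet:
    """The bundled reference-case parameter set (freshly built each call)."""
    return _parameters_from_document(dict(_default_document()))
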