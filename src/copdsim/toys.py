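"""Analytically solvable toy parameter sets for verification.

These fixtures collapse the model to chains with closed-form answers:

* ``geometric`` — a single living stage with a constant death probability
  ``q``; remaining lifetime is geometric, so expected (undiscounted)
  life-years equal ``1/q`` under the full-cycle accrual convention.
* ``two-stage`` — GOLD1 -> GOLD2 with constant progression probability and
  no death; GOLD2 occupancy at cycle ``t`` is ``1 - (1 - p)^t``.
* ``default-small`` — the bundled reference-case set (published scalar
  values with the synthetic reconstructed tables).
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    ENTRY_AGE_MIN,
    N_STAGES,
    ParameterSet,
    default_parameters,
)

__all__ = ["make_toy_parameters"]

# enough cycles that the geometric tail is below double precision
_TOY_MAX_AGE = ENTRY_AGE_MIN + 600


def _toy_base(
    death_q: float,
    progression_p: float,
    utility: float,
    cost: float,
    discount_rate: float,
    quit_prob: float,
    relapse_prob: float,
    max_age: int,
) -> ParameterSet:
    bands = np.array([ENTRY_AGE_MIN])
    prog = np.zeros((N_STAGES, 1, 2))
    prog[0, :, :] = progression_p  # only GOLD1 progresses in the toys
    age_dist = np.zeros((N_STAGES, 1))
    age_dist[:, 0] = 1.0
    return ParameterSet(
        severity_distribution=np.array([1.0, 0.0, 0.0, 0.0]),
        age_class_lowers=np.array([ENTRY_AGE_MIN]),
        age_distribution=age_dist,
        quit_prob=quit_prob,
        relapse_prob=relapse_prob,
        exacerbation_prob=np.zeros((N_STAGES, 2)),
        progression_prob=prog,
        death_prob=np.full((N_STAGES, 1, 2, 2), death_q),
        utility=np.full((N_STAGES, 2), utility),
        annual_cost=np.full(N_STAGES, cost),
        discount_rate=discount_rate,
        max_age=max_age,
        age_band_lowers=bands,
    )


def make_toy_parameters(kind: str, **overrides) -> ParameterSet:
    """Build a validated toy :class:`ParameterSet`.

    Parameters
    ----------
    kind
        ``"geometric"``, ``"two-stage"`` or ``"default-small"``.
    **overrides
        ``death_q``, ``progression_p``, ``utility``, ``cost``,
        ``discount_rate``, ``quit_prob``, ``relapse_prob``, ``max_age``
        (toy kinds only).  Values violating the model invariants raise a
        validation error.
    """
    if kind == "default-small":
        if overrides:
            raise ValueError("default-small takes no overrides")
        return default_parameters()
    if kind not in ("geometric", "two-stage"):
        raise ValueError(f"unknown toy kind {kind!r}")
    defaults = dict(
        death_q=0.2 if kind == "geometric" else 0.0,
        progression_p=0.0 if kind == "geometric" else 0.1,
        utility=1.0,
        cost=0.0,
        discount_rate=0.0,
        quit_prob=0.0,
        relapse_prob=0.0,
        max_age=_TOY_MAX_AGE,
    )
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown overrides: {sorted(unknown)}")
    defaults.update(overrides)
    return _toy_base(**defaults).validate()
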