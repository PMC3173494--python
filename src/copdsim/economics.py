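"""Incremental cost-effectiveness between two simulated arms.

The incremental cost-effectiveness ratio (ICER) of an intervention versus a
comparator is ``(Δcost + programme_cost) / ΔQALY``, where Δ denotes the
intervention-minus-comparator difference in mean discounted outcomes and the
programme cost is charged once per cohort member at entry, undiscounted,
regardless of quit success.  Negative ICERs denote savings per QALY gained.
Results are flagged against the NICE willingness-to-pay threshold of
20,000 GBP/QALY.
"""

from __future__ import annotations

import dataclasses
import math

from .engine import CohortOutcome

__all__ = ["NICE_THRESHOLD", "IncrementalResult", "compute_icer", "compare_arms",
           "format_icer"]

NICE_THRESHOLD = 20_000.0


@dataclasses.dataclass
class IncrementalResult:
    """Arm-vs-arm differences (intervention minus comparator) and the ICER."""

    delta_cost: float
    delta_life_years: float
    delta_qalys: float
    programme_cost: float
    icer: float  # NaN when undefined (zero QALY difference)
    icer_defined: bool
    below_nice_threshold: bool
    note: str = ""

    def icer_at(self, programme_cost: float) -> float:
        """Re-price the same deltas under a different programme cost."""
        return compute_icer(self.delta_cost, self.delta_qalys, programme_cost)


def compute_icer(delta_cost: float, delta_qaly: float, programme_cost: float = 0.0) -> float:
    """ICER in GBP per QALY: ``(delta_cost + programme_cost) / delta_qaly``.

    A zero QALY difference makes the ratio undefined; the sentinel ``NaN``
    is returned so dominance bookkeeping can proceed without exceptions.
    """
    if programme_cost < 0:
        raise ValueError(f"programme_cost must be non-negative, got {programme_cost}")
    if delta_qaly == 0:
        return math.nan
    return (delta_cost + programme_cost) / delta_qaly


def format_icer(icer: float) -> str:
    """Display form: nearest integer GBP/QALY, or ``undefined``."""
    return "undefined" if math.isnan(icer) else f"{round(icer):d}"


def compare_arms(
    intervention: CohortOutcome,
    comparator: CohortOutcome,
    programme_cost: float = 0.0,
) -> IncrementalResult:
    """Incremental outcomes of an intervention arm versus its comparator.

    Both arms must stem from identically initialised cohorts of the same
    size (paired comparison); a size mismatch is an error.
    """
    if intervention.n != comparator.n:
        raise ValueError(
            f"arm sizes differ ({intervention.n} vs {comparator.n}); "
            "deltas would not be paired-comparable"
        )
    d_cost = intervention.mean_cost - comparator.mean_cost
    # life-years are reported undiscounted; discounting applies to costs and
    # QALYs only, per the NICE reference-case convention
    d_ly = (
        intervention.mean_life_years_undiscounted
        - comparator.mean_life_years_undiscounted
    )
    d_qaly = intervention.mean_qalys - comparator.mean_qalys
    icer = compute_icer(d_cost, d_qaly, programme_cost)
    defined = not math.isnan(icer)
    return IncrementalResult(
        delta_cost=d_cost,
        delta_life_years=d_ly,
        delta_qalys=d_qaly,
        programme_cost=programme_cost,
        icer=icer,
        icer_defined=defined,
        below_nice_threshold=bool(defined and icer < NICE_THRESHOLD),
        note="" if defined else "undefined ICER: zero QALY difference between arms",
    )
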