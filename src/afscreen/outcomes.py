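"""Cohort aggregation and incremental (device vs. no-device) outcomes.

The headline economic quantity is the signed cost per prevented stroke:
total cost difference between matched cohorts divided by the difference in
stroke counts.  Prevented counts are reported as raw signed differences —
Monte-Carlo noise can make them negative at low-risk scores — and a ratio
with a zero denominator is reported as undefined (``None``), not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import CohortResult

__all__ = ["CohortSummary", "ArmComparison", "summarize", "compare", "cost_per_prevented"]


@dataclass(frozen=True)
class CohortSummary:
    """Whole-simulation aggregates of one (score, arm) cohort."""

    score: int
    arm_label: str
    ecg_confirmation: float
    n: int
    average_cost: float  # discounted EUR per patient
    total_strokes: int  # nonfatal + fatal
    nonfatal_strokes: int
    fatal_strokes: int


@dataclass(frozen=True)
class ArmComparison:
    """Incremental outcomes of a device arm versus the no-device reference."""

    score: int
    ecg_confirmation: float
    cost_difference: float  # (device avg - reference avg) x n, EUR
    prevented_strokes: int  # reference - device; may be negative
    prevented_fatal_strokes: int
    cost_per_prevented_stroke: float | None  # None when prevented == 0
    cost_per_prevented_fatal_stroke: float | None


def summarize(result: CohortResult) -> CohortSummary:
    if result.n < 1 or len(result.cost_per_patient) == 0:
        raise ValueError("cannot summarize an empty cohort")
    nonfatal = int(result.nonfatal_strokes.sum())
    fatal = int(result.fatal_strokes.sum())
    return CohortSummary(
        score=result.score,
        arm_label=result.arm.label,
        ecg_confirmation=result.arm.ecg_confirmation if result.arm.has_device else 0.0,
        n=result.n,
        average_cost=float(result.cost_per_patient.mean()),
        total_strokes=nonfatal + fatal,
        nonfatal_strokes=nonfatal,
        fatal_strokes=fatal,
    )


def cost_per_prevented(cost_difference: float, prevented: int) -> float | None:
    """Signed ratio; undefined (None) when nothing was prevented or caused."""
    if prevented == 0:
        return None
    return cost_difference / prevented


def compare(reference: CohortSummary, intervention: CohortSummary) -> ArmComparison:
    """Incremental outcomes of ``intervention`` (device) vs. ``reference``.

    The cost difference is reconstructed as per-patient average x n, matching
    the published "sum of the costs for all the patients in each group".
    """
    if reference.score != intervention.score:
        raise ValueError(
            f"score mismatch: {reference.score} vs {intervention.score}"
        )
    if reference.n != intervention.n:
        raise ValueError(f"cohort size mismatch: {reference.n} vs {intervention.n}")
    cost_difference = (intervention.average_cost - reference.average_cost) * reference.n
    prevented = reference.total_strokes - intervention.total_strokes
    prevented_fatal = reference.fatal_strokes - intervention.fatal_strokes
    return ArmComparison(
        score=reference.score,
        ecg_confirmation=intervention.ecg_confirmation,
        cost_difference=cost_difference,
        prevented_strokes=prevented,
        prevented_fatal_strokes=prevented_fatal,
        cost_per_prevented_stroke=cost_per_prevented(cost_difference, prevented),
        cost_per_prevented_fatal_stroke=cost_per_prevented(cost_difference, prevented_fatal),
    )
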