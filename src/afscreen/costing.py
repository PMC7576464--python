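"""Translate patient-year events into discounted euros.

Cost components per patient-year: EUR 67.23 per physician visit with ECG
diagnostics, EUR 1226.40 per year on NOAC therapy, the post-stroke schedule
(EUR 15,753 in the stroke year, declining thereafter; a fatal stroke incurs
the year-1 cost once), and EUR 1995 per major bleeding event.  The one-time
device price (EUR 437.65) is charged at baseline in the device arm only.

Discounting uses the factor (1 + rate)^-(t - 1): the first cycle and the
baseline device purchase are undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import CostParameters

__all__ = ["CostLedger", "cycle_cost", "discount", "patient_total_cost"]


def discount(amount: float, year: int, rate: float) -> float:
    """Present value of ``amount`` incurred in cycle ``year`` (1-based)."""
    if year < 1:
        raise ValueError(f"cycle year must be >= 1, got {year}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return amount / (1.0 + rate) ** (year - 1)


def _components(outcome, costs: CostParameters) -> tuple[float, float, float, float]:
    """(visits, noac, stroke, bleeding) undiscounted euros for one cycle."""
    visits = outcome.ecg_visits * costs.visit_and_diagnostics_cost
    noac = costs.noac_annual_cost if outcome.on_noac_this_year else 0.0
    stroke = 0.0
    if outcome.post_stroke_year is not None:
        if outcome.post_stroke_year > len(costs.stroke_cost_schedule):
            raise ValueError(
                f"post-stroke year {outcome.post_stroke_year} exceeds the "
                f"{len(costs.stroke_cost_schedule)}-year cost schedule"
            )
        stroke = costs.stroke_cost_schedule[outcome.post_stroke_year - 1]
    bleeding = costs.bleeding_cost if outcome.bleeding else 0.0
    return visits, noac, stroke, bleeding


def cycle_cost(outcome, state=None, costs: CostParameters | None = None) -> float:
    """Undiscounted cost of one patient-year.

    ``state`` is accepted for interface symmetry with the engine but is not
    needed: everything cost-relevant is recorded on the outcome.
    """
    if costs is None:  # allow cycle_cost(outcome, costs)
        outcome, costs = outcome, state
        if not isinstance(costs, CostParameters):
            raise TypeError("cycle_cost needs CostParameters")
    return sum(_components(outcome, costs))


@dataclass(frozen=True)
class CostLedger:
    """Per-patient cost breakdown; category fields are discounted euros."""

    device: float
    visits: float
    noac: float
    stroke: float
    bleeding: float
    per_year_undiscounted: tuple[float, ...]
    per_year_discounted: tuple[float, ...]

    @property
    def total_discounted(self) -> float:
        return self.device + self.visits + self.noac + self.stroke + self.bleeding

    @property
    def total_undiscounted(self) -> float:
        return self.device + sum(self.per_year_undiscounted)


def patient_total_cost(history, arm, costs: CostParameters, rate: float) -> CostLedger:
    """Accumulate one patient's history into a discounted :class:`CostLedger`.

    The device price is added once iff the patient is in the device arm; each
    year's event costs are discounted by the cycle year.
    """
    device = costs.device_cost if arm.has_device else 0.0
    visits_d = noac_d = stroke_d = bleed_d = 0.0
    per_year_und: list[float] = []
    per_year_disc: list[float] = []
    for outcome in history:
        visits, noac, stroke, bleeding = _components(outcome, costs)
        f = discount(1.0, outcome.year, rate)
        visits_d += visits * f
        noac_d += noac * f
        stroke_d += stroke * f
        bleed_d += bleeding * f
        total = visits + noac + stroke + bleeding
        per_year_und.append(total)
        per_year_disc.append(total * f)
    return CostLedger(
        device=device,
        visits=visits_d,
        noac=noac_d,
        stroke=stroke_d,
        bleeding=bleed_d,
        per_year_undiscounted=tuple(per_year_und),
        per_year_discounted=tuple(per_year_disc),
    )
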