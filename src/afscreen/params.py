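"""Model parameters for the AF screening cost-effectiveness simulation.

All score-indexed quantities run over the CHA₂DS₂-VASc stroke-risk score
0..9.  Rates are expressed "per 100 person-years" and are applied as annual
transition probabilities ``p = rate / 100`` in the one-year-cycle model.
Proportions and probabilities are dimensionless values in [0, 1].

Parameter values are kept unrounded internally; rounding to 4 decimals (for
rate vectors) or whole euros (for report tables) is display-only.

The published inputs are: AF prevalence and incidence by score, stroke
incidence in untreated AF, device sensitivity and false-positive rate, ECG
confirmation scenarios, yearly standard-care detection, stroke case fatality
by treatment status, non-stroke mortality, and the cost block (device, ECG
visit, anticoagulation, post-stroke care, major bleeding).  Three vectors are
derived rather than taken directly:

* stroke incidence without AF  = untreated-AF incidence / relative risk (2.42),
* stroke incidence on NOAC     = untreated-AF incidence x (1 - 0.66),
* yearly standard-care detection = device sensitivity x (unmonitored AF
  detection rate / monitored AF detection rate) = 0.93 x 2.6 / 6.7.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

__all__ = [
    "N_SCORES",
    "InvalidParameterError",
    "ScoreVector",
    "ParameterSet",
    "CostParameters",
    "derive_no_af_incidence",
    "derive_noac_incidence",
    "derive_standard_care_detection",
    "sum_visit_cost",
    "build_stroke_cost_schedule",
    "validate",
    "default_parameters",
    "default_costs",
    "default_config",
    "dump_default_config",
    "params_from_config",
    "costs_from_config",
    "load_config",
]

#: number of CHA2DS2-VASc scores represented (0..9)
N_SCORES = 10


class InvalidParameterError(ValueError):
    """A model parameter violates its domain constraints."""


# ---------------------------------------------------------------------------
# score-indexed vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreVector:
    """Ten non-negative values indexed by CHA2DS2-VASc score 0..9.

    Used both for proportions (e.g. baseline AF prevalence) and for rates per
    100 person-years (e.g. stroke incidence).  The container enforces length
    and non-negativity; range checks that depend on the interpretation
    (proportion vs. rate) live in :meth:`check_proportion` /
    :meth:`check_rate_per_100` and are applied by :func:`validate`.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) != N_SCORES:
            raise InvalidParameterError(
                f"ScoreVector needs exactly {N_SCORES} entries (scores 0..9), "
                f"got {len(vals)}"
            )
        for s, v in enumerate(vals):
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"ScoreVector entry for score {s} must be finite and >= 0, got {v}"
                )

    def __getitem__(self, score: int) -> float:
        return self.values[score]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return N_SCORES

    def rounded(self, ndigits: int = 4) -> tuple[float, ...]:
        """Display rounding; internal values stay unrounded."""
        return tuple(round(v, ndigits) for v in self.values)

    def check_proportion(self, name: str) -> list[str]:
        return [
            f"{name}[{s}] must lie in [0, 1], got {v}"
            for s, v in enumerate(self.values)
            if not 0.0 <= v <= 1.0
        ]

    def check_rate_per_100(self, name: str) -> list[str]:
        return [
            f"{name}[{s}] is a rate per 100 person-years and must be < 100, got {v}"
            for s, v in enumerate(self.values)
            if v >= 100.0
        ]


def _as_score_vector(v: "ScoreVector | Sequence[float]") -> ScoreVector:
    return v if isinstance(v, ScoreVector) else ScoreVector(tuple(v))


# ---------------------------------------------------------------------------
# derivations
# ---------------------------------------------------------------------------


def derive_no_af_incidence(
    untreated: ScoreVector | Sequence[float], relative_risk: float
) -> ScoreVector:
    """Stroke incidence without AF from the untreated-AF incidence.

    AF carries a ``relative_risk``-fold (default 2.42) excess stroke risk, so
    the incidence in patients without AF is the untreated-AF incidence divided
    by that ratio, score by score.
    """
    if relative_risk <= 0:
        raise InvalidParameterError(
            f"relative_risk must be > 0, got {relative_risk}"
        )
    untreated = _as_score_vector(untreated)
    return ScoreVector(tuple(v / relative_risk for v in untreated))


def derive_noac_incidence(
    untreated: ScoreVector | Sequence[float], risk_reduction: float
) -> ScoreVector:
    """Stroke incidence on anticoagulation (NOAC).

    Oral anticoagulation reduces stroke risk by ``risk_reduction`` (default
    0.66, i.e. two-thirds), so the treated incidence is
    ``untreated x (1 - risk_reduction)``.
    """
    if not 0.0 <= risk_reduction <= 1.0:
        raise InvalidParameterError(
            f"risk_reduction must lie in [0, 1], got {risk_reduction}"
        )
    untreated = _as_score_vector(untreated)
    return ScoreVector(tuple(v * (1.0 - risk_reduction) for v in untreated))


def derive_standard_care_detection(
    device_sensitivity: float, unmonitored_rate: float, monitored_rate: float
) -> float:
    """Yearly probability that undiagnosed AF is found in routine care.

    The device sensitivity is scaled by the ratio of AF detection rates in
    unmonitored vs. actively monitored individuals (2.6 vs. 6.7 newly
    diagnosed AF cases per 100 person-years in the source screening study):
    0.93 x 2.6 / 6.7 = 0.3609 (4 d.p.).
    """
    if monitored_rate <= 0:
        raise InvalidParameterError(
            f"monitored_rate must be > 0, got {monitored_rate}"
        )
    return device_sensitivity * (unmonitored_rate / monitored_rate)


def sum_visit_cost(components: Iterable[float]) -> float:
    """Sum the single cost factors of one physician visit with diagnostics."""
    components = list(components)
    for c in components:
        if c < 0:
            raise InvalidParameterError(f"visit cost component must be >= 0, got {c}")
    return math.fsum(components)


def build_stroke_cost_schedule(
    anchors: Iterable[tuple[int, float]], horizon: int
) -> tuple[float, ...]:
    """Per-year post-stroke cost schedule from published anchor years.

    ``anchors`` are (year, cost) pairs with years in 1..``horizon``; entry ``k``
    of the result is the cost incurred in the k-th year after a stroke.  Years
    between two anchors are filled by geometric (log-linear) interpolation,

        c(y) = c_a * (c_b / c_a) ** ((y - a) / (b - a)),

    which reproduces every anchor exactly, is positive throughout and is
    non-increasing whenever the anchors are non-increasing.  Years outside the
    anchored range take the nearest anchor's value.
    """
    if horizon < 1:
        raise InvalidParameterError(f"horizon must be >= 1, got {horizon}")
    pairs = sorted((int(y), float(c)) for y, c in anchors)
    if not pairs:
        raise InvalidParameterError("at least one (year, cost) anchor is required")
    years = [y for y, _ in pairs]
    if len(set(years)) != len(years):
        raise InvalidParameterError(f"duplicate anchor years in {years}")
    for y, c in pairs:
        if not 1 <= y <= horizon:
            raise InvalidParameterError(
                f"anchor year {y} outside 1..{horizon}"
            )
        if c <= 0:
            raise InvalidParameterError(f"anchor cost must be > 0, got {c} at year {y}")

    schedule = [0.0] * horizon
    # constant extension before the first and after the last anchor
    for y in range(1, years[0] + 1):
        schedule[y - 1] = pairs[0][1]
    for y in range(years[-1], horizon + 1):
        schedule[y - 1] = pairs[-1][1]
    for (a, ca), (b, cb) in zip(pairs, pairs[1:]):
        for y in range(a, b + 1):
            frac = (y - a) / (b - a)
            schedule[y - 1] = ca * (cb / ca) ** frac
    return tuple(schedule)


# ---------------------------------------------------------------------------
# defaults (published base case)
# ---------------------------------------------------------------------------

PREVALENCE = (0.01, 0.015, 0.034, 0.067, 0.118, 0.182, 0.255, 0.302, 0.403, 0.492)
AF_INCIDENCE = (0.17, 0.21, 0.49, 0.94, 1.65, 2.31, 2.75, 3.39, 4.09, 6.71)
STROKE_INCIDENCE_UNTREATED = (0.2, 0.6, 2.5, 3.7, 5.5, 8.4, 11.4, 13.1, 12.6, 14.44)

RELATIVE_STROKE_RISK_AF = 2.42
NOAC_RISK_REDUCTION = 0.66

#: AF detection rates (per 100 person-years) in unmonitored vs. actively
#: monitored individuals, used to derive the standard-care detection rate.
UNMONITORED_AF_DETECTION_RATE = 2.6
MONITORED_AF_DETECTION_RATE = 6.7

DEFAULT_STROKE_COST_ANCHORS = ((1, 15753.0), (2, 4480.0), (10, 1481.0))
VISIT_COST_COMPONENTS = (13.20, 12.90, 9.52, 9.96, 21.65)


@dataclass(frozen=True)
class ParameterSet:
    """All transition probabilities and scenario settings of the model.

    Score-indexed vectors accept any sequence of 10 values and are coerced to
    :class:`ScoreVector`.  ``stroke_incidence_no_af`` and
    ``stroke_incidence_noac`` may be given explicitly; by default they are
    derived from ``stroke_incidence_untreated`` via
    :func:`derive_no_af_incidence` / :func:`derive_noac_incidence`.

    Two annual probabilities the published model prices but does not state are
    configurable here: ``other_mortality_treated_af`` (default 0.111, the same
    as untreated AF — conservative in that anticoagulation is not credited
    with a non-stroke survival benefit) and ``bleed_prob_on_noac`` (default
    0.02/year while on NOAC; off-therapy bleeding defaults to 0).
    """

    prevalence: ScoreVector = PREVALENCE
    af_incidence: ScoreVector = AF_INCIDENCE
    stroke_incidence_untreated: ScoreVector = STROKE_INCIDENCE_UNTREATED
    stroke_incidence_no_af: ScoreVector | None = None
    stroke_incidence_noac: ScoreVector | None = None

    device_sensitivity: float = 0.93
    device_false_positive: float = 0.002
    ecg_confirmation: float = 1.0
    misdiagnosis_clearance: float = 1.0
    standard_care_detection: float = derive_standard_care_detection(
        0.93, UNMONITORED_AF_DETECTION_RATE, MONITORED_AF_DETECTION_RATE
    )

    stroke_mortality_no_af: float = 0.34
    stroke_mortality_untreated: float = 0.63
    stroke_mortality_treated: float = 0.42
    other_mortality_no_af: float = 0.06
    other_mortality_untreated_af: float = 0.111
    other_mortality_treated_af: float = 0.111

    bleed_prob_on_noac: float = 0.02
    bleed_prob_off_noac: float = 0.0

    relative_stroke_risk_af: float = RELATIVE_STROKE_RISK_AF
    noac_risk_reduction: float = NOAC_RISK_REDUCTION

    horizon_years: int = 10
    discount_rate: float = 0.03
    cohort_size: int = 30_000

    def __post_init__(self) -> None:
        set_ = object.__setattr__
        set_(self, "prevalence", _as_score_vector(self.prevalence))
        set_(self, "af_incidence", _as_score_vector(self.af_incidence))
        set_(
            self,
            "stroke_incidence_untreated",
            _as_score_vector(self.stroke_incidence_untreated),
        )
        if self.stroke_incidence_no_af is None:
            set_(
                self,
                "stroke_incidence_no_af",
                derive_no_af_incidence(
                    self.stroke_incidence_untreated, self.relative_stroke_risk_af
                ),
            )
        else:
            set_(self, "stroke_incidence_no_af", _as_score_vector(self.stroke_incidence_no_af))
        if self.stroke_incidence_noac is None:
            set_(
                self,
                "stroke_incidence_noac",
                derive_noac_incidence(
                    self.stroke_incidence_untreated, self.noac_risk_reduction
                ),
            )
        else:
            set_(self, "stroke_incidence_noac", _as_score_vector(self.stroke_incidence_noac))

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with ``changes`` applied (derived vectors re-derived
        unless explicitly supplied)."""
        current = dataclasses.asdict(self)
        for key in ("stroke_incidence_no_af", "stroke_incidence_noac"):
            if key not in changes:
                current[key] = None  # re-derive from (possibly new) inputs
        for key in (
            "prevalence",
            "af_incidence",
            "stroke_incidence_untreated",
            "stroke_incidence_no_af",
            "stroke_incidence_noac",
        ):
            if isinstance(current.get(key), dict):
                current[key] = ScoreVector(current[key]["values"])
        current.update(changes)
        return ParameterSet(**current)


@dataclass(frozen=True)
class CostParameters:
    """Cost block in euros (statutory-health-insurance perspective).

    ``stroke_cost_schedule`` entry ``k`` (0-based ``k-1``) is the cost in the
    k-th year after a stroke; the default is interpolated between the
    published anchors EUR 15,753 (year 1), 4,480 (year 2) and 1,481 (year 10).
    The NOAC price uses the unrounded published figure EUR 1226.40/year.
    """

    device_cost: float = 437.65
    visit_and_diagnostics_cost: float = sum_visit_cost(VISIT_COST_COMPONENTS)
    noac_annual_cost: float = 1226.40
    stroke_cost_schedule: tuple[float, ...] = field(
        default_factory=lambda: build_stroke_cost_schedule(
            DEFAULT_STROKE_COST_ANCHORS, 10
        )
    )
    bleeding_cost: float = 1995.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "stroke_cost_schedule", tuple(float(c) for c in self.stroke_cost_schedule)
        )

    def replace(self, **changes) -> "CostParameters":
        return dataclasses.replace(self, **changes)


def default_parameters() -> ParameterSet:
    """The published base-case transition probabilities."""
    return ParameterSet()


def default_costs() -> CostParameters:
    """The published base-case cost block."""
    return CostParameters()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_PROBABILITY_FIELDS = (
    "device_sensitivity",
    "device_false_positive",
    "ecg_confirmation",
    "misdiagnosis_clearance",
    "standard_care_detection",
    "stroke_mortality_no_af",
    "stroke_mortality_untreated",
    "stroke_mortality_treated",
    "other_mortality_no_af",
    "other_mortality_untreated_af",
    "other_mortality_treated_af",
    "bleed_prob_on_noac",
    "bleed_prob_off_noac",
    "noac_risk_reduction",
    "discount_rate",  # checked >= 0 only, below
)


def validate(
    params: ParameterSet, costs: CostParameters
) -> tuple[ParameterSet, CostParameters]:
    """Check every invariant; raise :class:`InvalidParameterError` listing all
    violations (field name and offending value), else return the pair."""
    errors: list[str] = []

    errors += params.prevalence.check_proportion("prevalence")
    for name in (
        "af_incidence",
        "stroke_incidence_untreated",
        "stroke_incidence_no_af",
        "stroke_incidence_noac",
    ):
        errors += getattr(params, name).check_rate_per_100(name)

    for name in _PROBABILITY_FIELDS:
        v = getattr(params, name)
        if name == "discount_rate":
            if v < 0:
                errors.append(f"discount_rate must be >= 0, got {v}")
        elif not 0.0 <= v <= 1.0:
            errors.append(f"{name} must lie in [0, 1], got {v}")

    if params.relative_stroke_risk_af <= 0:
        errors.append(
            f"relative_stroke_risk_af must be > 0, got {params.relative_stroke_risk_af}"
        )
    if params.horizon_years < 1:
        errors.append(f"horizon_years must be >= 1, got {params.horizon_years}")
    if params.cohort_size < 1:
        errors.append(f"cohort_size must be >= 1, got {params.cohort_size}")

    for s in range(N_SCORES):
        if params.stroke_incidence_noac[s] > params.stroke_incidence_untreated[s]:
            errors.append(
                "stroke_incidence_noac must not exceed stroke_incidence_untreated "
                f"at score {s}: {params.stroke_incidence_noac[s]} > "
                f"{params.stroke_incidence_untreated[s]}"
            )
        if params.stroke_incidence_no_af[s] > params.stroke_incidence_untreated[s]:
            errors.append(
                "stroke_incidence_no_af must not exceed stroke_incidence_untreated "
                f"at score {s}: {params.stroke_incidence_no_af[s]} > "
                f"{params.stroke_incidence_untreated[s]}"
            )

    for name in (
        "device_cost",
        "visit_and_diagnostics_cost",
        "noac_annual_cost",
        "bleeding_cost",
    ):
        v = getattr(costs, name)
        if v < 0:
            errors.append(f"{name} must be >= 0, got {v}")
    sched = costs.stroke_cost_schedule
    if len(sched) != params.horizon_years:
        errors.append(
            f"stroke_cost_schedule length {len(sched)} must equal "
            f"horizon_years {params.horizon_years}"
        )
    for k, c in enumerate(sched):
        if c < 0:
            errors.append(f"stroke_cost_schedule[{k}] must be >= 0, got {c}")
    if any(b > a for a, b in zip(sched, sched[1:])):
        errors.append(f"stroke_cost_schedule must be non-increasing, got {sched}")

    if errors:
        raise InvalidParameterError("; ".join(errors))
    return params, costs


# ---------------------------------------------------------------------------
# configuration file support
# ---------------------------------------------------------------------------

_EXPERIMENT_DEFAULTS = {
    "scores": list(range(1, 10)),
    "confirmations": [1.0, 0.75, 0.5],
    "n": 30_000,
    "base_seed": 20201006,
    "sensitivity_grid": [0.86, 0.93, 1.0],
    "false_positive_grid": [0.002, 0.01, 0.05],
    "sensitivity_confirmation": 0.75,
}


def default_config() -> dict:
    """Default configuration dictionary with sections params/costs/experiment."""
    p = default_parameters()
    c = default_costs()
    params_section = {}
    for f in dataclasses.fields(ParameterSet):
        v = getattr(p, f.name)
        params_section[f.name] = list(v) if isinstance(v, ScoreVector) else v
    costs_section = {
        "device_cost": c.device_cost,
        "visit_components": list(VISIT_COST_COMPONENTS),
        "noac_annual_cost": c.noac_annual_cost,
        "stroke_cost_anchors": [list(a) for a in DEFAULT_STROKE_COST_ANCHORS],
        "bleeding_cost": c.bleeding_cost,
    }
    return {
        "params": params_section,
        "costs": costs_section,
        "experiment": dict(_EXPERIMENT_DEFAULTS),
    }


def dump_default_config() -> str:
    """Default configuration as a YAML document."""
    return yaml.safe_dump(default_config(), sort_keys=False)


def params_from_config(section: dict | None) -> ParameterSet:
    section = dict(section or {})
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(section) - known
    if unknown:
        raise InvalidParameterError(f"unknown params keys: {sorted(unknown)}")
    return ParameterSet(**section)


def costs_from_config(section: dict | None, horizon: int = 10) -> CostParameters:
    section = dict(section or {})
    kwargs = {}
    if "visit_components" in section:
        kwargs["visit_and_diagnostics_cost"] = sum_visit_cost(
            section.pop("visit_components")
        )
    if "stroke_cost_anchors" in section:
        kwargs["stroke_cost_schedule"] = build_stroke_cost_schedule(
            [tuple(a) for a in section.pop("stroke_cost_anchors")], horizon
        )
    known = {"device_cost", "visit_and_diagnostics_cost", "noac_annual_cost",
             "stroke_cost_schedule", "bleeding_cost"}
    unknown = set(section) - known
    if unknown:
        raise InvalidParameterError(f"unknown costs keys: {sorted(unknown)}")
    kwargs.update(section)
    return CostParameters(**kwargs)


def load_config(source) -> tuple[ParameterSet, CostParameters, dict]:
    """Load a YAML config (path, file object, or pre-parsed dict).

    Returns a validated ``(ParameterSet, CostParameters, experiment_section)``
    triple; the experiment section is merged over its defaults and interpreted
    by :mod:`afscreen.experiments`.
    """
    if isinstance(source, dict):
        raw = source
    else:
        if hasattr(source, "read"):
            raw = yaml.safe_load(source.read())
        else:
            with open(source, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
    raw = raw or {}
    unknown = set(raw) - {"params", "costs", "experiment"}
    if unknown:
        raise InvalidParameterError(f"unknown config sections: {sorted(unknown)}")
    params = params_from_config(raw.get("params"))
    costs = costs_from_config(raw.get("costs"), horizon=params.horizon_years)
    validate(params, costs)
    experiment = dict(_EXPERIMENT_DEFAULTS)
    experiment.update(raw.get("experiment") or {})
    return params, costs, experiment
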