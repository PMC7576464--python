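"""Annual-cycle state-transition simulator.

Each simulated year a patient passes, in order, through

1. AF onset (only while AF-free), at the score-specific AF incidence;
2. the screening cascade — in the device arm an undetected-AF patient can
   raise a true device alert (sensitivity) which an ECG visit confirms with
   the arm's confirmation probability, and an AF-free patient can raise a
   false alert (false-positive rate) which the ECG visit clears; any AF that
   is still undetected afterwards can be found by standard care (both arms);
3. endpoint resolution — stroke (fatal with the treatment-status-specific
   case fatality) or, exclusively, death from other causes; a major-bleeding
   event is drawn independently on top of whichever endpoint occurred.

The endpoints sit at the end of each cycle, downstream of the screening
cascade, so a detection made this year already changes this year's endpoint
probabilities: a treatment-eligible patient detected in the cascade faces the
on-therapy stroke risk, case fatality, bleeding risk and NOAC cost from the
detection year onward.  A stroke in undetected AF also triggers diagnosis,
but since it *is* the endpoint, therapy then starts with the next cycle.
Death is absorbing and ends the patient's simulation.

Random-number discipline: every cycle consumes exactly eight uniform draws
(one for onset, three in the screening cascade, four at endpoint resolution)
regardless of which branches are taken, and :func:`simulate_patient` draws a
patient's full ``8 x horizon`` block up front.  Consumption is therefore
independent of the realised history, which makes common-random-number
comparisons across arms exact: with the same seed, two arms see identical
uniforms in identical roles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .cohort import AFStatus, Arm, PatientState, generate_cohort
from .costing import patient_total_cost
from .params import CostParameters, ParameterSet

__all__ = [
    "CycleOutcome",
    "TransitionProbabilities",
    "CohortResult",
    "transition_probabilities",
    "screen_and_detect",
    "resolve_endpoint",
    "simulate_patient",
    "simulate_cohort",
]


@dataclass(slots=True)
class CycleOutcome:
    """Events and bookkeeping of one patient-year.

    ``post_stroke_year`` is the position in the post-stroke cost schedule
    charged this year (1 in a stroke year, incrementing afterwards), or
    ``None`` for patients who never had a stroke.  ``ecg_visits`` counts the
    physician-visit-with-ECG cost units incurred this year: one per device
    alert (true or false) and one for a standard-care detection, so an
    unconfirmed alert followed by standard-care detection in the same year
    costs two visits.
    """

    year: int = 0
    af_onset: bool = False
    device_true_alert: bool = False
    device_false_alert: bool = False
    ecg_visits: int = 0
    confirmed: bool = False
    standard_care_detected: bool = False
    stroke: str = "none"  # 'none' | 'nonfatal' | 'fatal'
    other_death: bool = False
    bleeding: bool = False
    on_noac_this_year: bool = False
    post_stroke_year: int | None = None


@dataclass(frozen=True, slots=True)
class TransitionProbabilities:
    """All per-year transition probabilities for one patient, given their
    current status and arm.  ``p_confirm`` is the probability that the ECG
    visit after a device alert resolves it correctly: the confirmation
    probability for true AF, the misdiagnosis-clearance probability for a
    false alert."""

    p_af_onset: float = 0.0
    p_true_alert: float = 0.0
    p_false_alert: float = 0.0
    p_confirm: float = 0.0
    p_standard_detect: float = 0.0
    p_stroke: float = 0.0
    p_stroke_fatal: float = 0.0
    p_other_death: float = 0.0
    p_bleed: float = 0.0


def transition_probabilities(
    state: PatientState, arm: Arm, params: ParameterSet
) -> TransitionProbabilities:
    """Map a patient's current status to their annual transition probabilities.

    Rates per 100 person-years enter as ``rate / 100`` (plain annual-cycle
    probabilities).  Screening probabilities are nonzero only where the
    corresponding event can occur: true alerts require the device arm and
    undetected AF, false alerts the device arm and no AF, standard-care
    detection any undetected AF (both arms).
    """
    if not state.alive:
        raise ValueError("transition probabilities are undefined for a dead patient")
    s = state.score
    status = state.af_status
    device = arm.has_device

    if status is AFStatus.NO_AF:
        return TransitionProbabilities(
            p_af_onset=params.af_incidence[s] / 100.0,
            p_false_alert=params.device_false_positive if device else 0.0,
            p_confirm=params.misdiagnosis_clearance,
            p_stroke=params.stroke_incidence_no_af[s] / 100.0,
            p_stroke_fatal=params.stroke_mortality_no_af,
            p_other_death=params.other_mortality_no_af,
            p_bleed=params.bleed_prob_off_noac,
        )
    if status is AFStatus.AF_UNDETECTED:
        return TransitionProbabilities(
            p_true_alert=params.device_sensitivity if device else 0.0,
            p_confirm=arm.ecg_confirmation,
            p_standard_detect=params.standard_care_detection,
            p_stroke=params.stroke_incidence_untreated[s] / 100.0,
            p_stroke_fatal=params.stroke_mortality_untreated,
            p_other_death=params.other_mortality_untreated_af,
            p_bleed=params.bleed_prob_off_noac,
        )
    if status is AFStatus.AF_DETECTED_UNTREATED:
        return TransitionProbabilities(
            p_stroke=params.stroke_incidence_untreated[s] / 100.0,
            p_stroke_fatal=params.stroke_mortality_untreated,
            p_other_death=params.other_mortality_untreated_af,
            p_bleed=params.bleed_prob_off_noac,
        )
    return TransitionProbabilities(
        p_stroke=params.stroke_incidence_noac[s] / 100.0,
        p_stroke_fatal=params.stroke_mortality_treated,
        p_other_death=params.other_mortality_treated_af,
        p_bleed=params.bleed_prob_on_noac,
    )


def _promote_to_detected(state: PatientState) -> None:
    state.af_status = (
        AFStatus.AF_DETECTED_TREATED
        if state.treatment_eligible
        else AFStatus.AF_DETECTED_UNTREATED
    )


def screen_and_detect(
    state: PatientState,
    arm: Arm,
    probs: TransitionProbabilities,
    rng,
    outcome: CycleOutcome | None = None,
) -> CycleOutcome:
    """Run the screening cascade for one year, mutating ``state`` in place.

    Consumes exactly three uniform draws from ``rng`` (alert, ECG resolution,
    standard-care detection) whether or not each is needed.  Returns the
    partially filled :class:`CycleOutcome` (alert/visit/detection fields).
    """
    u_alert, u_resolve, u_detect = rng.random(3)
    out = outcome if outcome is not None else CycleOutcome()

    if state.af_status is AFStatus.AF_UNDETECTED:
        if u_alert < probs.p_true_alert:
            out.device_true_alert = True
            out.ecg_visits += 1
            if u_resolve < probs.p_confirm:
                out.confirmed = True
                _promote_to_detected(state)
        if state.af_status is AFStatus.AF_UNDETECTED and u_detect < probs.p_standard_detect:
            # standard care finds AF (both arms), including after a missed or
            # unconfirmed device alert in the same year
            out.standard_care_detected = True
            out.confirmed = True
            out.ecg_visits += 1
            _promote_to_detected(state)
    elif state.af_status is AFStatus.NO_AF:
        if u_alert < probs.p_false_alert:
            out.device_false_alert = True
            out.ecg_visits += 1
            # the ECG clears the misdiagnosis (probability 1 in the base
            # case); the patient stays AF-free either way — an uncleared
            # false alert is simply re-drawable next year
            _ = u_resolve < probs.p_confirm
    # detected patients generate no further screening events or visit costs
    return out


def resolve_endpoint(
    state: PatientState,
    probs: TransitionProbabilities,
    rng,
    outcome: CycleOutcome | None = None,
) -> CycleOutcome:
    """Resolve the year's endpoint, mutating ``state`` in place.

    Stroke is drawn first; a stroke is fatal with ``p_stroke_fatal``.  Only
    stroke-free patients face the other-cause death draw (the endpoints are
    mutually exclusive).  A major-bleeding event is drawn independently for
    every patient alive at the start of the year.  A nonfatal stroke in
    undetected AF leads to diagnosis (and therapy, if eligible) from the next
    cycle.  Consumes exactly four uniform draws.
    """
    u_stroke, u_fatal, u_death, u_bleed = rng.random(4)
    out = outcome if outcome is not None else CycleOutcome()

    if u_stroke < probs.p_stroke:
        state.stroke_count += 1
        state.years_since_last_stroke = 1  # a new stroke restarts the cost clock
        if u_fatal < probs.p_stroke_fatal:
            out.stroke = "fatal"
            state.alive = False
            state.death_cause = "stroke"
        else:
            out.stroke = "nonfatal"
            if state.af_status is AFStatus.AF_UNDETECTED:
                _promote_to_detected(state)
    else:
        if state.years_since_last_stroke is not None:
            state.years_since_last_stroke += 1
        if u_death < probs.p_other_death:
            out.other_death = True
            state.alive = False
            state.death_cause = "other"

    if u_bleed < probs.p_bleed:
        out.bleeding = True

    out.post_stroke_year = state.years_since_last_stroke
    return out


class _BlockDraws:
    """Sequential view over a pre-drawn array of uniforms, mimicking the
    ``Generator.random`` call pattern the cascade functions use."""

    __slots__ = ("u", "i")

    def __init__(self, u: np.ndarray) -> None:
        self.u = u
        self.i = 0

    def random(self, k: int | None = None):
        i = self.i
        if k is None:
            self.i = i + 1
            return self.u[i]
        self.i = i + k
        return self.u[i : i + k]


def simulate_patient(
    initial: PatientState, arm: Arm, params: ParameterSet, rng: np.random.Generator
) -> list[CycleOutcome]:
    """Simulate one patient for up to ``params.horizon_years`` annual cycles.

    The initial state is copied, never mutated.  Exactly
    ``8 * horizon_years`` uniforms are drawn from ``rng`` up front, so RNG
    consumption per patient is constant even when death truncates the history.
    """
    state = dataclasses.replace(initial)
    horizon = params.horizon_years
    draws = _BlockDraws(rng.random(8 * horizon))
    history: list[CycleOutcome] = []

    for year in range(1, horizon + 1):
        u_onset = draws.random()
        outcome = CycleOutcome(year=year)

        if state.af_status is AFStatus.NO_AF and u_onset < params.af_incidence[state.score] / 100.0:
            state.af_status = AFStatus.AF_UNDETECTED
            outcome.af_onset = True

        probs = transition_probabilities(state, arm, params)
        screen_and_detect(state, arm, probs, draws, outcome)
        # the endpoint comes after the cascade: a detection made above puts
        # the patient on therapy for this year's stroke/death/bleeding draws
        # (and this year's NOAC cost) already
        endpoint_probs = transition_probabilities(state, arm, params)
        outcome.on_noac_this_year = state.af_status is AFStatus.AF_DETECTED_TREATED
        resolve_endpoint(state, endpoint_probs, draws, outcome)
        history.append(outcome)
        if not state.alive:
            break
    return history


@dataclass
class CohortResult:
    """Per-patient outcomes of one simulated (score, arm) cohort."""

    score: int
    arm: Arm
    n: int
    seed: object
    cost_per_patient: np.ndarray  # discounted 10-year total, EUR
    nonfatal_strokes: np.ndarray  # events per patient
    fatal_strokes: np.ndarray  # 0/1 per patient
    category_totals: dict[str, float]  # discounted EUR summed over the cohort
    histories: list[list[CycleOutcome]] | None = None


def simulate_cohort(
    score: int,
    arm: Arm,
    params: ParameterSet,
    costs: CostParameters,
    n: int,
    seed,
    collect_histories: bool = False,
) -> CohortResult:
    """Generate and simulate a full cohort; reproducible per seed.

    The seed is split into one stream for cohort generation and one for the
    annual-cycle simulation.  Running two arms with the same seed therefore
    uses identical patients *and* positionally identical uniforms — the
    common-random-numbers mode; the published base case instead seeds every
    (score, arm) cohort independently.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_cohort, ss_sim = ss.spawn(2)
    patients = generate_cohort(score, n, params, np.random.default_rng(ss_cohort))
    rng = np.random.default_rng(ss_sim)

    cost = np.zeros(n)
    nonfatal = np.zeros(n, dtype=np.int64)
    fatal = np.zeros(n, dtype=np.int64)
    categories = {"device": 0.0, "visits": 0.0, "noac": 0.0, "stroke": 0.0, "bleeding": 0.0}
    histories: list[list[CycleOutcome]] | None = [] if collect_histories else None

    for i, patient in enumerate(patients):
        history = simulate_patient(patient, arm, params, rng)
        ledger = patient_total_cost(history, arm, costs, params.discount_rate)
        cost[i] = ledger.total_discounted
        for oc in history:
            if oc.stroke == "nonfatal":
                nonfatal[i] += 1
            elif oc.stroke == "fatal":
                fatal[i] = 1
        categories["device"] += ledger.device
        categories["visits"] += ledger.visits
        categories["noac"] += ledger.noac
        categories["stroke"] += ledger.stroke
        categories["bleeding"] += ledger.bleeding
        if histories is not None:
            histories.append(history)

    return CohortResult(
        score=score,
        arm=arm,
        n=n,
        seed=seed if isinstance(seed, int) else None,
        cost_per_patient=cost,
        nonfatal_strokes=nonfatal,
        fatal_strokes=fatal,
        category_totals=categories,
        histories=histories,
    )
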