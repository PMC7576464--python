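import math

import numpy as np
import pytest

from afscreen import (
    AFStatus,
    NO_DEVICE,
    PatientState,
    device_arm,
    resolve_endpoint,
    screen_and_detect,
    simulate_cohort,
    simulate_patient,
    summarize,
    transition_probabilities,
)
from afscreen.cohort import Sex

AF_RANK = {
    AFStatus.NO_AF: 0,
    AFStatus.AF_UNDETECTED: 1,
    AFStatus.AF_DETECTED_UNTREATED: 2,
    AFStatus.AF_DETECTED_TREATED: 2,
}


def undetected(score, sex=Sex.MALE):
    return PatientState(score=score, sex=sex, af_status=AFStatus.AF_UNDETECTED)


class TestTransitionProbabilities:
    def test_untreated_af_high_score(self, params):
        probs = transition_probabilities(undetected(9), NO_DEVICE, params)
        assert probs.p_stroke == pytest.approx(0.1444)
        assert probs.p_stroke_fatal == 0.63
        assert probs.p_other_death == 0.111
        assert probs.p_standard_detect == pytest.approx(0.93 * 2.6 / 6.7)

    def test_treated_af_low_score(self, params):
        state = PatientState(score=1, af_status=AFStatus.AF_DETECTED_TREATED)
        probs = transition_probabilities(state, NO_DEVICE, params)
        assert probs.p_stroke == pytest.approx(0.00204)
        assert probs.p_stroke_fatal == 0.42
        assert probs.p_bleed == params.bleed_prob_on_noac

    def test_no_af_score_zero_parameters(self, params):
        state = PatientState(score=0)
        probs = transition_probabilities(state, NO_DEVICE, params)
        # unrounded 0.2 / 2.42 / 100; prints as 0.0826 per 100 person-years
        assert probs.p_stroke == pytest.approx(0.000826, abs=5e-7)
        assert probs.p_stroke_fatal == 0.34
        assert probs.p_other_death == 0.06

    def test_device_alert_probabilities_keyed_to_arm_and_status(self, params):
        dev = device_arm(0.75)
        assert transition_probabilities(undetected(5), dev, params).p_true_alert == 0.93
        assert transition_probabilities(undetected(5), NO_DEVICE, params).p_true_alert == 0.0
        no_af = PatientState(score=5)
        assert transition_probabilities(no_af, dev, params).p_false_alert == 0.002
        assert transition_probabilities(no_af, NO_DEVICE, params).p_false_alert == 0.0
        treated = PatientState(score=5, af_status=AFStatus.AF_DETECTED_TREATED)
        probs = transition_probabilities(treated, dev, params)
        assert probs.p_true_alert == probs.p_standard_detect == 0.0

    def test_dead_patient_rejected(self, params):
        dead = PatientState(score=5, alive=False, death_cause="other")
        with pytest.raises(ValueError):
            transition_probabilities(dead, NO_DEVICE, params)


class TestScreenAndDetect:
    def test_certain_cascade_detects_and_treats_in_one_cycle(self, params):
        sure = params.replace(device_sensitivity=1.0)
        state = undetected(4)
        probs = transition_probabilities(state, device_arm(1.0), sure)
        out = screen_and_detect(state, device_arm(1.0), probs, np.random.default_rng(0))
        assert out.device_true_alert and out.confirmed and out.ecg_visits == 1
        assert state.af_status is AFStatus.AF_DETECTED_TREATED

    def test_score1_female_detected_but_not_treated(self, params):
        sure = params.replace(device_sensitivity=1.0)
        state = undetected(1, sex=Sex.FEMALE)
        probs = transition_probabilities(state, device_arm(1.0), sure)
        screen_and_detect(state, device_arm(1.0), probs, np.random.default_rng(0))
        assert state.af_status is AFStatus.AF_DETECTED_UNTREATED

    def test_no_detection_channels_leaves_state_unchanged(self, params):
        off = params.replace(device_sensitivity=0.0, standard_care_detection=0.0)
        state = undetected(6)
        probs = transition_probabilities(state, device_arm(1.0), off)
        out = screen_and_detect(state, device_arm(1.0), probs, np.random.default_rng(1))
        assert state.af_status is AFStatus.AF_UNDETECTED
        assert out.ecg_visits == 0

    def test_detection_probability_composition_matches_closed_form(self, params):
        # device alert then confirmation, else standard care:
        # p = s*c + (1 - s*c) * d with s=0.93, c=0.75, d=0.3609...
        s, c, d = 0.93, 0.75, params.standard_care_detection
        expected = s * c + (1 - s * c) * d
        arm = device_arm(c)
        rng = np.random.default_rng(12345)
        n = 100_000
        detected = 0
        for _ in range(n):
            state = undetected(5)
            probs = transition_probabilities(state, arm, params)
            screen_and_detect(state, arm, probs, rng)
            detected += state.af_status.detected
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(detected / n - expected) < 4 * se
        assert expected == pytest.approx(0.8067, abs=5e-5)

    def test_false_alert_logs_visit_but_never_changes_status(self, params):
        always = params.replace(device_false_positive=1.0)
        state = PatientState(score=3)
        probs = transition_probabilities(state, device_arm(1.0), always)
        out = screen_and_detect(state, device_arm(1.0), probs, np.random.default_rng(2))
        assert out.device_false_alert and out.ecg_visits == 1
        assert state.af_status is AFStatus.NO_AF


class TestResolveEndpoint:
    def test_zero_stroke_probability_yields_no_strokes(self, params, costs):
        zero = params.replace(
            stroke_incidence_untreated=(0.0,) * 10,
            stroke_incidence_no_af=(0.0,) * 10,
            stroke_incidence_noac=(0.0,) * 10,
        )
        result = simulate_cohort(7, NO_DEVICE, zero, costs, 2_000, 8)
        assert result.nonfatal_strokes.sum() == 0 and result.fatal_strokes.sum() == 0

    def test_certain_fatal_stroke_kills_everyone_in_year_one(self, params):
        lethal = params.replace(
            stroke_incidence_untreated=(99.999,) * 10,
            stroke_mortality_untreated=1.0,
            standard_care_detection=0.0,
        )
        rng = np.random.default_rng(3)
        history = simulate_patient(undetected(5), NO_DEVICE, lethal, rng)
        assert len(history) == 1
        assert history[0].stroke == "fatal"
        assert history[0].post_stroke_year == 1

    def test_one_year_event_frequencies_match_probabilities(self, params):
        # untreated-AF score 8 cohort for a single cycle
        n = 30_000
        p_stroke = params.stroke_incidence_untreated[8] / 100
        p_fatal = params.stroke_mortality_untreated
        rng = np.random.default_rng(99)
        strokes = fatals = 0
        no_detect = params.replace(device_sensitivity=0.0, standard_care_detection=0.0)
        one_year = no_detect.replace(horizon_years=1)
        for _ in range(n):
            history = simulate_patient(undetected(8), NO_DEVICE, one_year, rng)
            if history[0].stroke != "none":
                strokes += 1
            if history[0].stroke == "fatal":
                fatals += 1
        se_s = math.sqrt(p_stroke * (1 - p_stroke) / n) * n
        assert abs(strokes - n * p_stroke) < 4 * se_s
        p_f = p_stroke * p_fatal
        se_f = math.sqrt(p_f * (1 - p_f) / n) * n
        assert abs(fatals - n * p_f) < 4 * se_f

    def test_nonfatal_stroke_in_undetected_af_triggers_diagnosis(self, params):
        sure_stroke = params.replace(
            stroke_incidence_untreated=(99.999,) * 10,
            stroke_mortality_untreated=0.0,
            device_sensitivity=0.0,
            standard_care_detection=0.0,
        )
        state = undetected(6)
        probs = transition_probabilities(state, NO_DEVICE, sure_stroke)
        out = resolve_endpoint(state, probs, np.random.default_rng(4))
        assert out.stroke == "nonfatal"
        assert state.af_status is AFStatus.AF_DETECTED_TREATED
        assert state.years_since_last_stroke == 1

    def test_stroke_and_other_death_are_mutually_exclusive(self, params):
        rng = np.random.default_rng(5)
        busy = params.replace(
            stroke_incidence_untreated=(50.0,) * 10,
            other_mortality_untreated_af=0.5,
        )
        for _ in range(2_000):
            state = undetected(5)
            probs = transition_probabilities(state, NO_DEVICE, busy)
            out = resolve_endpoint(state, probs, rng)
            assert not (out.stroke != "none" and out.other_death)


class TestSimulatePatient:
    def test_event_free_patient_completes_full_horizon(self, params):
        quiet = params.replace(
            prevalence=(0.0,) * 10,
            af_incidence=(0.0,) * 10,
            stroke_incidence_no_af=(0.0,) * 10,
            stroke_incidence_untreated=(0.0,) * 10,
            other_mortality_no_af=0.0,
        )
        history = simulate_patient(
            PatientState(score=3), NO_DEVICE, quiet, np.random.default_rng(6)
        )
        assert len(history) == 10
        assert all(
            oc.stroke == "none" and not oc.other_death and oc.ecg_visits == 0
            for oc in history
        )

    def test_certain_other_death_gives_single_cycle(self, params):
        doomed = params.replace(other_mortality_no_af=1.0, prevalence=(0.0,) * 10,
                                af_incidence=(0.0,) * 10)
        history = simulate_patient(
            PatientState(score=3), NO_DEVICE, doomed, np.random.default_rng(7)
        )
        assert len(history) == 1 and history[0].other_death

    def test_seeded_history_is_reproducible(self, params):
        initial = undetected(5)
        h1 = simulate_patient(initial, device_arm(0.75), params, np.random.default_rng(42))
        h2 = simulate_patient(initial, device_arm(0.75), params, np.random.default_rng(42))
        assert h1 == h2

    def test_af_knowledge_is_monotone_and_death_absorbing(self, params):
        rng = np.random.default_rng(8)
        for _ in range(300):
            state = PatientState(score=7)
            history = simulate_patient(state, device_arm(0.75), params, rng)
            # re-simulate cheaply by checking recorded outcome ordering instead:
            assert len(history) <= params.horizon_years
            terminal = [oc for oc in history if oc.stroke == "fatal" or oc.other_death]
            if terminal:
                assert terminal[-1] is history[-1]  # nothing after death
                assert len(terminal) == 1

    def test_no_screening_events_after_detection(self, params):
        # AF knowledge is monotone: once diagnosed (by cascade or by a
        # nonfatal stroke), a patient raises no further alerts, standard-care
        # detections or screening visit costs
        rng = np.random.default_rng(9)
        arm = device_arm(0.5)
        for _ in range(300):
            history = simulate_patient(undetected(4), arm, params, rng)
            detected = False
            for oc in history:
                if detected:
                    assert oc.ecg_visits == 0
                    assert not oc.device_true_alert
                    assert not oc.standard_care_detected
                if oc.confirmed or oc.standard_care_detected or oc.stroke == "nonfatal":
                    detected = True


class TestSimulateCohort:
    def test_seeded_rerun_is_bit_identical(self, params, costs):
        a = simulate_cohort(6, device_arm(0.75), params, costs, 2_000, 77)
        b = simulate_cohort(6, device_arm(0.75), params, costs, 2_000, 77)
        assert np.array_equal(a.cost_per_patient, b.cost_per_patient)
        assert np.array_equal(a.nonfatal_strokes, b.nonfatal_strokes)
        assert np.array_equal(a.fatal_strokes, b.fatal_strokes)

    def test_zero_everything_gives_zero_summary(self, costs):
        import afscreen

        params = afscreen.default_parameters().replace(
            prevalence=(0.0,) * 10,
            af_incidence=(0.0,) * 10,
            stroke_incidence_untreated=(0.0,) * 10,
            stroke_incidence_no_af=(0.0,) * 10,
            stroke_incidence_noac=(0.0,) * 10,
            other_mortality_no_af=0.0,
        )
        result = simulate_cohort(5, NO_DEVICE, params, costs, 500, 1)
        summary = summarize(result)
        assert summary.average_cost == 0.0
        assert summary.total_strokes == 0

    def test_one_cycle_mean_cost_matches_event_tree_oracle(self, params, costs):
        # treated score-8 cohort, one cycle, no discounting: the event tree
        # enumerates to  E[cost] = noac + p_stroke*sched[0] + p_bleed*bleed
        one = params.replace(horizon_years=1, prevalence=(1.0,) * 10)
        one_costs = costs.replace(stroke_cost_schedule=(costs.stroke_cost_schedule[0],))
        # force everyone straight onto therapy: certain detection
        sure = one.replace(device_sensitivity=1.0, standard_care_detection=1.0,
                           discount_rate=0.0)
        n = 30_000
        result = simulate_cohort(8, device_arm(1.0), sure, one_costs, n, 4242)
        p_stroke = sure.stroke_incidence_noac[8] / 100
        expected = (
            costs.device_cost
            + sure.device_sensitivity * costs.visit_and_diagnostics_cost
            + one_costs.noac_annual_cost
            + p_stroke * one_costs.stroke_cost_schedule[0]
            + sure.bleed_prob_on_noac * costs.bleeding_cost
        )
        mean = result.cost_per_patient.mean()
        se = result.cost_per_patient.std(ddof=1) / math.sqrt(n)
        assert abs(mean - expected) < 3 * se

    def test_degenerate_device_equals_no_device_up_to_device_price(self, params, costs):
        blind = params.replace(device_sensitivity=0.0, device_false_positive=0.0)
        seed = 1234
        dev = simulate_cohort(5, device_arm(1.0), blind, costs, 3_000, seed)
        ref = simulate_cohort(5, NO_DEVICE, blind, costs, 3_000, seed)
        assert np.array_equal(dev.nonfatal_strokes, ref.nonfatal_strokes)
        assert np.array_equal(dev.fatal_strokes, ref.fatal_strokes)
        np.testing.assert_allclose(
            dev.cost_per_patient - ref.cost_per_patient, costs.device_cost, rtol=1e-12
        )

    def test_screening_reduces_strokes_at_high_scores(self, params, costs):
        # directional treatment benefit, replicated across seeds
        for seed in (11, 12, 13):
            dev = simulate_cohort(6, device_arm(1.0), params, costs, 10_000, 9000 + seed)
            ref = simulate_cohort(6, NO_DEVICE, params, costs, 10_000, 7000 + seed)
            n_dev = dev.nonfatal_strokes.sum() + dev.fatal_strokes.sum()
            n_ref = ref.nonfatal_strokes.sum() + ref.fatal_strokes.sum()
            assert n_dev < n_ref, f"seed {seed}: {n_dev} >= {n_ref}"
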