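# Model and methods

## State-transition structure

Each simulated patient carries a fixed CHA₂DS₂-VASc score (1..9), a sex, and
an AF status in {no AF, AF undetected, AF detected untreated, AF detected
treated}. One cycle is one year; the horizon is 10 years; death is
absorbing. Within a cycle the order is:

1. **AF onset** (AF-free patients only), probability `af_incidence[s]/100`.
   AF is incurable: no transition ever leaves the AF branch.
2. **Screening cascade.** Device arm, undetected AF: device alert with
   probability = sensitivity (0.93 base); every alert triggers one ECG
   visit; the ECG confirms AF with the arm's confirmation probability
   (1.00/0.75/0.50 scenarios). Device arm, no AF: false alert with
   probability 0.002, one ECG visit, cleared with probability 1. Both arms:
   AF still undetected after the device step is found by standard care with
   probability 0.3609/year (one ECG visit). A same-year unconfirmed alert
   and standard-care detection are independent draws, so the per-year
   detection probability in the 75%-confirmation device arm composes to
   0.93×0.75 + (1−0.93×0.75)×0.3609 ≈ 0.807.
3. **Endpoint.** Stroke first (annual probability = status-specific
   incidence/100), fatal with the status-specific case fatality; otherwise
   the other-cause death draw; the two endpoints are mutually exclusive
   within a cycle. Major bleeding is drawn independently for every patient
   alive at cycle start and can coincide with any endpoint.

**Therapy timing.** The endpoints sit at the end of the cycle, downstream of
the screening cascade, so a detection made this year already applies the
on-therapy stroke incidence, case fatality, bleeding risk and NOAC cost to
this year's endpoint. This is the reading of the decision tree that the
package adopts; the alternative (therapy from the next cycle) systematically
understates the screening effect — it raises no-device fatal strokes at
score 9 by ~15% and cuts prevented strokes at score 8 by ~20% relative to
the same-cycle variant, as the package's own comparison runs show. A stroke
in *undetected* AF also triggers diagnosis, but since the stroke is the
endpoint itself, therapy then starts with the next cycle; this
stroke-triggered diagnosis incurs no separate visit cost. Once detected, a
patient never generates screening events or visit costs again.

**Treatment rule.** Detected AF starts NOAC for males from score 1 and
females from score 2; detected females at score 1 remain untreated (the
score-1 cohort is half female for exactly this reason; sex is irrelevant and
not drawn at other scores). Recurrent strokes are allowed every year at the
status-specific incidence; a new stroke resets the post-stroke cost clock.

## Parameters

Score-indexed vectors (index 0..9; score 0 is representable but not
simulated, since below the treatment threshold a comparison is moot):

| parameter | values | note |
|---|---|---|
| AF prevalence | 0.01 … 0.492 | baseline, enters undetected |
| AF incidence /100 py | 0.17 … 6.71 | annual onset |
| stroke incidence, untreated AF /100 py | 0.2 … 14.44 | |
| stroke incidence, no AF | untreated ÷ 2.42 | derived; AF relative risk |
| stroke incidence, on NOAC | untreated × (1 − 0.66) | derived; NOAC risk reduction |

Scalars: device sensitivity 0.93 (grid 0.86/0.93/1.00), false-positive rate
0.002 (grid 0.002/0.01/0.05), ECG confirmation 1.00/0.75/0.50,
misdiagnosis clearance 1.0, standard-care detection 0.93 × 2.6/6.7 = 0.3609
(kept fixed when device sensitivity is varied — it describes the no-device
care pathway), stroke case fatality 0.34 (no AF) / 0.63 (untreated AF) /
0.42 (treated), other-cause mortality 0.06 (no AF) / 0.111 (untreated AF).
Internal values are unrounded; 4-decimal vectors are display-only.

Costs (EUR): device 437.65 once at baseline (undiscounted, no replacement);
ECG visit + diagnostics 67.23 (= 13.20 + 12.90 + 9.52 + 9.96 + 21.65);
NOAC 1226.40/year (unrounded figure), charged for every year on therapy
including the detection year; major bleeding 1995 per event; post-stroke
care by year since stroke, anchored at 15,753 (year 1), 4,480 (year 2) and
1,481 (year 10) with geometric (log-linear) interpolation between anchors —
year 5 evaluates to 4480 × (1481/4480)^(3/8) ≈ 2958. A fatal stroke incurs
the year-1 cost once. Discounting multiplies year-*t* costs by
(1.03)^−(t−1): the first cycle is undiscounted.

Two probabilities the model needs but the published parameter set does not
state, both configurable:

* **other-cause mortality on treatment** — default 0.111, identical to
  untreated AF; deliberately conservative in that anticoagulation gets no
  non-stroke survival credit;
* **annual major-bleeding probability on NOAC** — default 0.02, applied only
  while on therapy (0 otherwise); at EUR 1995 per event this contributes
  ≈ EUR 40 per treated patient-year, small relative to drug cost.

## Random numbers and reproducibility

Each (score, arm, grid-variant) cohort is seeded by a
`numpy` `SeedSequence(base_seed, spawn_key=(score, arm, confirmation,
variant))`, split once for cohort generation and once for simulation.
Every simulated cycle consumes exactly eight uniforms in fixed roles (onset,
alert, ECG resolution, standard-care detection, stroke, fatality, other
death, bleeding), drawn as one block per patient up front. Consumption is
therefore independent of the realised history, and running two arms with
the *same* seed yields positionally aligned draws: with device sensitivity
and false-positive rate set to 0 the arms produce identical event histories
and per-patient costs differing exactly by the device price — the test suite
exercises this common-random-numbers property. The base case instead seeds
arms independently, matching how the published simulations were run, so
agreement with printed outcomes is statistical, never bit-exact.

## What the generator emulates — and what it does not

The synthetic cohort reproduces exactly the statistical structure the
analysis assumes: score-specific AF prevalence at entry, Bernoulli(1/2) sex
at score 1 (an exact-split option exists for variance reduction), everyone
alive, undiagnosed and stroke-free at baseline. It has **no** age structure,
no comorbidity covariates, no score progression over time, and general
mortality is flat 6%/year regardless of age — all simplifications inherited
from the model it implements. Passing tests therefore validate the
simulation machinery and its published parameterisation, not the external
validity of those epidemiological simplifications.

## Numerical and design choices

* Rates per 100 person-years convert to annual probabilities as `rate/100`
  (no exponential conversion): the derived vectors in the parameter tables
  are plain arithmetic on the printed rates, so this is the intended use.
* Event draws use strict `u < p` comparisons on [0,1) uniforms; degenerate
  probabilities 0 and 1 behave exactly.
* An uncleared false alert (clearance < 1, non-default) leaves the patient
  AF-free and re-drawable next year; the model has no "falsely treated"
  state.
* A patient with a prior stroke who dies of another cause still incurs that
  year's post-stroke cost (alive at cycle start); the clock never exceeds
  the horizon, so the schedule cannot be over-run.
* Cost ledgers keep per-category discounted totals; category additivity and
  discounted-equals-undiscounted at rate 0 are tested invariants.
* Ratios with a zero prevented-stroke denominator are reported as
  `undefined`, never as an error or an infinity.

## Problem sizes used by the test suite

Full-scale checks (30,000 patients per cohort, five seed replicates) cover
the three headline quantities: incremental cost per patient at score 1 with
75% confirmation, prevented strokes at score 8 with 75% confirmation, and
the no-device average cost at score 9 — bands of ±20% on costs and ±25% on
prevented-stroke differences absorb the two unstated probabilities above,
the unstated interpolation of intermediate stroke-cost years and RNG
differences, with the qualitative direction (devices cost more; screening
prevents strokes at high scores) required in every replicate. One-cycle
event frequencies are verified against the transition probabilities at
n = 10⁶ (4 binomial SE); smaller cohorts (200–10,000) exercise structural
invariants.

## Known limitations

* Absolute per-patient costs at *low* scores in the no-device arm fall well
  below the corresponding published table entries (≈ EUR 460 vs 873 at
  score 1) even though incremental costs, high-score absolute costs, stroke
  counts and prevented strokes all reproduce; the published low-score rows
  appear to contain a roughly constant per-patient cost offset present in
  both arms that no stated cost component accounts for. Incremental
  comparisons — the model's purpose — are unaffected.
* No QALYs, no indirect costs, no catheter ablation/cardioversion, no VKA
  therapy arm, no half-cycle correction, no within-year event dating.
* Nonfatal-stroke survivors carry no excess long-term mortality beyond the
  acute case fatality.
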