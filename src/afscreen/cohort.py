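"""Synthetic patient cohorts.

One simulated individual is a :class:`PatientState`: a fixed CHA₂DS₂-VASc
score, a sex (only decision-relevant at score 1, where anticoagulation is
initiated for males but not for females), and an evolving AF / diagnosis /
treatment status.  A cohort for a given score enters the model with AF
prevalence taken from the score-specific baseline prevalence; prevalent AF
starts *undetected* — finding it is precisely what the screening arm is for.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = ["AFStatus", "Sex", "PatientState", "Arm", "init_patient", "generate_cohort"]


class AFStatus(enum.IntEnum):
    """Health/diagnosis status.  AF is never cured, so the only legal moves
    are rightward: NO_AF -> AF_UNDETECTED -> detected (treated or not)."""

    NO_AF = 0
    AF_UNDETECTED = 1
    AF_DETECTED_UNTREATED = 2  # only females with score 1 (below therapy threshold)
    AF_DETECTED_TREATED = 3

    @property
    def has_af(self) -> bool:
        return self is not AFStatus.NO_AF

    @property
    def detected(self) -> bool:
        return self in (AFStatus.AF_DETECTED_UNTREATED, AFStatus.AF_DETECTED_TREATED)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(slots=True)
class PatientState:
    """One simulated individual's evolving state.

    ``years_since_last_stroke`` is ``None`` until a first stroke, then 1 in
    the stroke year and incremented every following simulated year (a new
    stroke resets it to 1); it indexes the post-stroke cost schedule.
    """

    score: int
    sex: Sex = Sex.MALE
    af_status: AFStatus = AFStatus.NO_AF
    alive: bool = True
    death_cause: str = "none"  # 'none' | 'stroke' | 'other'
    years_since_last_stroke: int | None = None
    stroke_count: int = 0

    @property
    def treatment_eligible(self) -> bool:
        """Anticoagulation is initiated for males from score 1 and for
        females from score 2 upward."""
        return self.score >= 2 or self.sex is Sex.MALE


@dataclass(frozen=True)
class Arm:
    """Study arm: screening with a PPG wrist device (with an ECG confirmation
    probability for device alerts) or standard care only."""

    label: str  # 'device' | 'no_device'
    ecg_confirmation: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in ("device", "no_device"):
            raise ValueError(f"arm label must be 'device' or 'no_device', got {self.label!r}")
        if not 0.0 <= self.ecg_confirmation <= 1.0:
            raise ValueError(
                f"ecg_confirmation must lie in [0, 1], got {self.ecg_confirmation}"
            )

    @property
    def has_device(self) -> bool:
        return self.label == "device"


NO_DEVICE = Arm("no_device")


def device_arm(ecg_confirmation: float = 1.0) -> Arm:
    return Arm("device", ecg_confirmation)


def _check_score(score: int) -> None:
    if not 1 <= score <= 9:
        raise ValueError(f"simulated scores run from 1 to 9, got {score}")


def init_patient(score: int, params, rng: np.random.Generator) -> PatientState:
    """Draw one baseline patient for ``score``.

    AF is present (undetected) with probability ``params.prevalence[score]``.
    At score 1 the sex is Bernoulli(1/2) because the therapy-initiation rule
    splits the score-1 stratum; at other scores sex does not affect any
    transition and is set to male without consuming a random draw.
    """
    _check_score(score)
    af = rng.random() < params.prevalence[score]
    sex = Sex.MALE
    if score == 1:
        sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
    return PatientState(
        score=score,
        sex=sex,
        af_status=AFStatus.AF_UNDETECTED if af else AFStatus.NO_AF,
    )


def generate_cohort(
    score: int,
    n: int,
    params,
    seed,
    exact_sex_split: bool = False,
) -> list[PatientState]:
    """Generate ``n`` independent baseline patients, reproducibly per seed.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`.  With ``exact_sex_split`` the score-1
    cohort is assigned exactly alternating sexes instead of independent
    Bernoulli(1/2) draws (a variance-reduction option; AF status is still
    drawn per patient).
    """
    _check_score(score)
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    patients = [init_patient(score, params, rng) for _ in range(n)]
    if exact_sex_split and score == 1:
        for i, p in enumerate(patients):
            p.sex = Sex.FEMALE if i % 2 else Sex.MALE
    return patients
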