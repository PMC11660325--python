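"""Fixed vocabularies: the 15 index symptoms and the outcome codes per sex.

The outcome model distinguishes cancer groups by the clinical specialty that
receives urgent referrals (breast, gynaecological, lung, upper GI, lower GI,
urological, prostate, haematological, other), plus death without a prior
cancer diagnosis, plus administrative censoring.  Breast and gynaecological
cancer are modelled for women only; prostate cancer for men only.  Male
breast and testicular cancers fall under ``other_cancer``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical symptom order used everywhere (cohort columns, coefficient
#: vectors, config files).
SYMPTOMS: tuple[str, ...] = (
    "abdominal_pain",
    "abdominal_bloating",
    "rectal_bleeding",
    "change_in_bowel_habit",
    "dyspepsia",
    "dysphagia",
    "jaundice",
    "dyspnoea",
    "haemoptysis",
    "haematuria",
    "fatigue",
    "night_sweats",
    "weight_loss",
    "breast_lump",
    "post_menopausal_bleeding",
)

N_SYMPTOMS = len(SYMPTOMS)

#: Symptoms that can only be recorded for women.
FEMALE_ONLY_SYMPTOMS: frozenset[str] = frozenset({"post_menopausal_bleeding"})

CANCER_GROUPS: tuple[str, ...] = (
    "breast",
    "gynaecological",
    "lung",
    "upper_gi",
    "lower_gi",
    "urological",
    "prostate",
    "haematological",
    "other_cancer",
)

NONCANCER_DEATH = "noncancer_death"
CENSORED = "censored"

OUTCOMES: tuple[str, ...] = CANCER_GROUPS + (NONCANCER_DEATH, CENSORED)

FEMALE = "F"
MALE = "M"
SEXES: tuple[str, str] = (FEMALE, MALE)

_FEMALE_CANCERS = (
    "breast",
    "gynaecological",
    "lung",
    "upper_gi",
    "lower_gi",
    "urological",
    "haematological",
    "other_cancer",
)
_MALE_CANCERS = (
    "lung",
    "upper_gi",
    "lower_gi",
    "urological",
    "prostate",
    "haematological",
    "other_cancer",
)


@dataclass(frozen=True)
class OutcomeVocabulary:
    """Ordered event codes applicable to one sex.

    Women have 8 cancer groups plus non-cancer death (9 event codes);
    men have 7 plus non-cancer death (8 event codes).
    """

    sex: str
    cancer_groups: tuple[str, ...] = field(init=False)
    event_codes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex code {self.sex!r}; expected one of {SEXES}")
        groups = _FEMALE_CANCERS if self.sex == FEMALE else _MALE_CANCERS
        object.__setattr__(self, "cancer_groups", groups)
        object.__setattr__(self, "event_codes", groups + (NONCANCER_DEATH,))

    def allows(self, outcome: str) -> bool:
        return outcome == CENSORED or outcome in self.event_codes


def outcomes_for_sex(sex: str) -> OutcomeVocabulary:
    return OutcomeVocabulary(sex)


AGE_MIN = 30.0
AGE_MAX = 99.0

#: One day expressed in months of 30.44 days (365.25 / 12).
DAYS_PER_MONTH = 30.44
ONE_DAY_MONTHS = 1.0 / DAYS_PER_MONTH
#: Same-day events are floored at half a day so log-time is always defined.
MIN_TIME_MONTHS = 0.5 / DAYS_PER_MONTH
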