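"""Shared fixtures: a known single-symptom ground truth and cohorts drawn
from it, reused across module tests to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from symptomrisk.hazards import ParametricCauseHazard
from symptomrisk.synthetic_cohort import AgeDistribution, GeneratorConfig, TrueModel, generate_cohort
from symptomrisk.vocab import N_SYMPTOMS, SYMPTOMS

RECOVERY_SYMPTOM = "haemoptysis"
TRUE_BETA = np.log(2.0)
TRUE_GAMMA = -0.2
TRUE_AGE_SLOPE_PER_DECADE = 0.3
TRUE_SMOKING = 0.4
TRUE_RATE = 0.002         # baseline hazard of the event cause, per month
TRUE_DEATH_RATE = 0.001


def make_recovery_truth() -> TrueModel:
    """One cancer cause with a decaying symptom effect, age and smoking
    effects, plus a competing flat death hazard; Weibull baselines so the
    truth lies exactly inside the fitted spline model class."""
    lhr = np.zeros(N_SYMPTOMS)
    tve = np.zeros(N_SYMPTOMS)
    j = SYMPTOMS.index(RECOVERY_SYMPTOM)
    lhr[j], tve[j] = TRUE_BETA, TRUE_GAMMA
    event = ParametricCauseHazard(
        outcome="lung", sex="F",
        baseline_coefs=np.array([np.log(TRUE_RATE), 1.0]),
        age_coefs=np.array([TRUE_AGE_SLOPE_PER_DECADE]),
        smoking_lhr=TRUE_SMOKING, symptom_lhr=lhr, symptom_tve=tve,
    )
    death = ParametricCauseHazard(
        outcome="noncancer_death", sex="F",
        baseline_coefs=np.array([np.log(TRUE_DEATH_RATE), 1.0]),
    )
    return TrueModel(causes={"F": {"lung": event, "noncancer_death": death}})


def make_recovery_config(n: int, seed: int) -> GeneratorConfig:
    return GeneratorConfig(
        n_patients=n, prop_reference=0.5,
        symptom_mix={RECOVERY_SYMPTOM: 1.0},
        prop_female=1.0, prop_ever_smoker=0.5,
        age_distribution=AgeDistribution(name="uniform", lo=30.0, hi=99.0),
        seed=seed,
    )


def true_params_in_fit_parameterization() -> dict[str, float]:
    """The ground-truth coefficients expressed on the fitted model's scale.

    The truth is linear in log time and in age, so the nonlinear spline
    coefficients are exactly zero; the fitted age basis column 1 is age in
    years and the fitted baseline intercept absorbs the age centering."""
    return {
        "baseline_intercept": np.log(TRUE_RATE) - TRUE_AGE_SLOPE_PER_DECADE * 6.0,
        "baseline_rcs1": 1.0,
        "baseline_rcs2": 0.0,
        "baseline_rcs3": 0.0,
        "age_rcs1": TRUE_AGE_SLOPE_PER_DECADE / 10.0,
        "age_rcs2": 0.0,
        "age_rcs3": 0.0,
        "age_rcs4": 0.0,
        "age_rcs5": 0.0,
        "ever_smoker": TRUE_SMOKING,
        RECOVERY_SYMPTOM: TRUE_BETA,
        f"{RECOVERY_SYMPTOM}:log_time": TRUE_GAMMA,
    }


@pytest.fixture(scope="session")
def recovery_truth() -> TrueModel:
    return make_recovery_truth()


@pytest.fixture(scope="session")
def recovery_cohort(recovery_truth):
    """50 000 patients from the known truth (fixed seed)."""
    return generate_cohort(make_recovery_config(50_000, seed=11), recovery_truth)
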