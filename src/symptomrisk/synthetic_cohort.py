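"""Synthetic primary-care cohort generation from a known ground truth.

The generator emulates the statistical structure of a UK primary-care
symptom cohort linked to cancer registration: a large reference group, 15
symptomatic sub-cohorts of very different sizes, ages 30-99 skewed young,
a binary ever-smoker flag, and competing outcomes (nine cancer groups and
non-cancer death) whose hazards vary by age, sex, smoking and index symptom
with symptom effects that decay in log time.

Each patient's outcome is produced by the same latent-failure-time
construction the analysis assumes: one latent time per applicable cause,
drawn by inverting that cause's cumulative hazard at an independent
unit-exponential draw, with the earliest latent time observed subject to
administrative censoring.  A cancer latent time falling within one day of
the death latent time is resolved to the cancer, mirroring how same-day
diagnosis/death registrations are handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .cohort_io import ADDITIONAL_SYMPTOM_COLUMN, COHORT_COLUMNS, validate_cohort
from .hazards import CovariatePattern, ParametricCauseHazard
from .vocab import (
    AGE_MAX,
    AGE_MIN,
    CANCER_GROUPS,
    CENSORED,
    DAYS_PER_MONTH,
    FEMALE,
    FEMALE_ONLY_SYMPTOMS,
    MALE,
    MIN_TIME_MONTHS,
    N_SYMPTOMS,
    NONCANCER_DEATH,
    ONE_DAY_MONTHS,
    SEXES,
    SYMPTOMS,
    outcomes_for_sex,
)

__all__ = [
    "AgeDistribution",
    "GeneratorConfig",
    "TrueModel",
    "ConfigError",
    "generate_cohort",
    "sample_first_event",
    "apply_observation_scheme",
]


class ConfigError(ValueError):
    """Generator configuration violated an invariant; the message names the field."""


@dataclass(frozen=True)
class AgeDistribution:
    """Named age-at-index distribution with support inside [30, 99] years.

    ``banded_uniform``: mixture of uniforms over age bands with given weights
    (the default emulates grouped-age cohort fractions).  ``uniform``: a
    single band.  ``fixed``: a degenerate point mass, useful for cohorts
    generated at one covariate pattern.
    """

    name: str
    bands: tuple[tuple[float, float], ...] = ()
    weights: tuple[float, ...] = ()
    age: float = 60.0
    lo: float = AGE_MIN
    hi: float = AGE_MAX

    def __post_init__(self) -> None:
        if self.name not in ("banded_uniform", "uniform", "fixed"):
            raise ConfigError(f"age_distribution.name: unknown distribution {self.name!r}")
        if self.name == "banded_uniform":
            if len(self.bands) != len(self.weights) or not self.bands:
                raise ConfigError("age_distribution: bands and weights must align and be non-empty")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ConfigError("age_distribution.weights: must sum to 1")
            for lo, hi in self.bands:
                if not (AGE_MIN <= lo < hi <= AGE_MAX):
                    raise ConfigError(f"age_distribution.bands: band ({lo}, {hi}) outside [30, 99]")
        elif self.name == "uniform":
            if not (AGE_MIN <= self.lo < self.hi <= AGE_MAX):
                raise ConfigError("age_distribution: uniform range outside [30, 99]")
        elif not (AGE_MIN <= self.age <= AGE_MAX):
            raise ConfigError("age_distribution.age: outside [30, 99]")

    def sample(self, n: int, rng: np.random.Generator) -> NDArray:
        if self.name == "fixed":
            return np.full(n, float(self.age))
        if self.name == "uniform":
            return rng.uniform(self.lo, self.hi, size=n)
        idx = rng.choice(len(self.bands), size=n, p=np.asarray(self.weights))
        lo = np.asarray([b[0] for b in self.bands])[idx]
        hi = np.asarray([b[1] for b in self.bands])[idx]
        return rng.uniform(lo, hi)

    def to_dict(self) -> dict:
        d: dict = {"name": self.name}
        if self.name == "banded_uniform":
            d["bands"] = [list(b) for b in self.bands]
            d["weights"] = list(self.weights)
        elif self.name == "uniform":
            d["lo"], d["hi"] = self.lo, self.hi
        else:
            d["age"] = self.age
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgeDistribution":
        return cls(
            name=d["name"],
            bands=tuple(tuple(b) for b in d.get("bands", [])),
            weights=tuple(d.get("weights", [])),
            age=d.get("age", 60.0),
            lo=d.get("lo", AGE_MIN),
            hi=d.get("hi", AGE_MAX),
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Marginal structure of the generated cohort."""

    n_patients: int
    prop_reference: float
    symptom_mix: Mapping[str, float]
    prop_female: float
    prop_ever_smoker: float
    age_distribution: AgeDistribution
    admin_censor_months: float = 18.0
    registry_end_uniform_months: tuple[float, float] | None = None
    seed: int = 0
    #: Optional extensions, off by default: fraction of symptomatic patients
    #: with a second index symptom, and fraction consulting for an additional
    #: studied symptom within 30 days of the index.
    prop_multi_symptom: float = 0.0
    prop_additional_symptom_30d: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients: must be a positive integer")
        for name in ("prop_reference", "prop_female", "prop_ever_smoker",
                     "prop_multi_symptom", "prop_additional_symptom_30d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: fraction {v} outside [0, 1]")
        mix = dict(self.symptom_mix)
        unknown = [s for s in mix if s not in SYMPTOMS]
        if unknown:
            raise ConfigError(f"symptom_mix: unknown symptoms {unknown}")
        if any(not 0.0 <= f <= 1.0 for f in mix.values()):
            raise ConfigError("symptom_mix: fractions must lie in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError(f"symptom_mix: fractions sum to {sum(mix.values())}, not 1")
        if self.admin_censor_months <= 0:
            raise ConfigError("admin_censor_months: must be positive")
        if self.registry_end_uniform_months is not None:
            lo, hi = self.registry_end_uniform_months
            if not 0 < lo <= hi:
                raise ConfigError("registry_end_uniform_months: need 0 < lo <= hi")
        object.__setattr__(self, "symptom_mix", mix)

    def symptom_probs(self, sex: str) -> NDArray:
        """Symptom mix for one sex, with female-only symptoms reallocated
        proportionally for men."""
        p = np.array([self.symptom_mix.get(s, 0.0) for s in SYMPTOMS])
        if sex == MALE:
            for s in FEMALE_ONLY_SYMPTOMS:
                p[SYMPTOMS.index(s)] = 0.0
            if p.sum() <= 0:
                raise ConfigError("symptom_mix: no symptoms applicable to men")
            p = p / p.sum()
        return p

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "prop_reference": self.prop_reference,
            "symptom_mix": dict(self.symptom_mix),
            "prop_female": self.prop_female,
            "prop_ever_smoker": self.prop_ever_smoker,
            "age_distribution": self.age_distribution.to_dict(),
            "admin_censor_months": self.admin_censor_months,
            "registry_end_uniform_months": (
                None if self.registry_end_uniform_months is None
                else list(self.registry_end_uniform_months)
            ),
            "seed": self.seed,
            "prop_multi_symptom": self.prop_multi_symptom,
            "prop_additional_symptom_30d": self.prop_additional_symptom_30d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        reg = d.get("registry_end_uniform_months")
        return cls(
            n_patients=int(d["n_patients"]),
            prop_reference=float(d["prop_reference"]),
            symptom_mix=dict(d["symptom_mix"]),
            prop_female=float(d["prop_female"]),
            prop_ever_smoker=float(d["prop_ever_smoker"]),
            age_distribution=AgeDistribution.from_dict(d["age_distribution"]),
            admin_censor_months=float(d.get("admin_censor_months", 18.0)),
            registry_end_uniform_months=None if reg is None else (float(reg[0]), float(reg[1])),
            seed=int(d.get("seed", 0)),
            prop_multi_symptom=float(d.get("prop_multi_symptom", 0.0)),
            prop_additional_symptom_30d=float(d.get("prop_additional_symptom_30d", 0.0)),
        )


@dataclass
class TrueModel:
    """Ground-truth cause-specific hazards, keyed by sex then outcome.

    Shares the hazard parameterization with fitted models, so parameter
    recovery can be checked coefficient by coefficient.
    """

    causes: dict[str, dict[str, ParametricCauseHazard]]

    def __post_init__(self) -> None:
        for sex, models in self.causes.items():
            if sex not in SEXES:
                raise ConfigError(f"TrueModel: unknown sex {sex!r}")
            vocab = outcomes_for_sex(sex)
            for outcome in models:
                if outcome not in vocab.event_codes:
                    raise ConfigError(
                        f"TrueModel: outcome {outcome!r} is not applicable to sex {sex!r}"
                    )
        self._check_hazard_positivity()

    def _check_hazard_positivity(self) -> None:
        """Numerically verify d(eta)/du > 0 on (0, 18] months for the
        reference pattern and every single-symptom pattern in the support."""
        t_grid = np.geomspace(MIN_TIME_MONTHS, 18.0, 50)
        for sex, models in self.causes.items():
            probs_ok = [None] + list(range(N_SYMPTOMS))
            for outcome, model in models.items():
                for s in probs_ok:
                    x = np.zeros(N_SYMPTOMS)
                    if s is not None:
                        if SYMPTOMS[s] in FEMALE_ONLY_SYMPTOMS and sex == MALE:
                            continue
                        x[s] = 1.0
                    h = model.hazard(t_grid, 60.0, 0, x)
                    if np.any(h <= 0):
                        raise ConfigError(
                            f"TrueModel: non-positive hazard for {sex}/{outcome} "
                            f"with symptom {None if s is None else SYMPTOMS[s]}"
                        )

    def outcomes(self, sex: str) -> tuple[str, ...]:
        return tuple(self.causes[sex])

    def to_dict(self) -> dict:
        return {
            sex: {outcome: m.to_dict() for outcome, m in models.items()}
            for sex, models in self.causes.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueModel":
        return cls(causes={
            sex: {outcome: ParametricCauseHazard.from_dict(m) for outcome, m in models.items()}
            for sex, models in d.items()
        })


# ---------------------------------------------------------------------------
# Sampling


def sample_first_event(
    pattern: CovariatePattern, truth: TrueModel, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one latent event time (months) per cause applicable to the
    pattern's sex, by inverse-cumulative-hazard sampling."""
    out: dict[str, float] = {}
    for outcome, model in truth.causes[pattern.sex].items():
        e = rng.exponential()
        t = model.inverse_cumulative_hazard(
            np.asarray([e]), pattern.age, pattern.ever_smoker, pattern.symptom_array
        )
        out[outcome] = float(t[0])
    return out


def _censoring_time(config: GeneratorConfig, rng: np.random.Generator, n: int = 1) -> NDArray:
    cens = np.full(n, float(config.admin_censor_months))
    if config.registry_end_uniform_months is not None:
        lo, hi = config.registry_end_uniform_months
        cens = np.minimum(cens, rng.uniform(lo, hi, size=n))
    return cens


def _resolve_observation(
    latent_names: list[str], latent_times: NDArray, cens: NDArray
) -> tuple[NDArray, NDArray]:
    """Vectorized first-event resolution with the same-day cancer/death tie.

    ``latent_times`` has shape (n_causes, n_patients).
    """
    is_cancer = np.array([name in CANCER_GROUPS for name in latent_names])
    first = np.argmin(latent_times, axis=0)
    n = latent_times.shape[1]
    t_first = latent_times[first, np.arange(n)]
    outcome = np.asarray(latent_names, object)[first]

    # same-day tie: the death latent time is first, but a cancer latent time
    # falls within one day of it (and inside follow-up) -> cancer diagnosis
    if NONCANCER_DEATH in latent_names and is_cancer.any():
        death_first = outcome == NONCANCER_DEATH
        if death_first.any():
            cancer_times = np.where(is_cancer[:, None], latent_times, np.inf)
            nearest = np.argmin(cancer_times, axis=0)
            t_cancer = cancer_times[nearest, np.arange(n)]
            tie = death_first & (t_cancer - t_first < ONE_DAY_MONTHS) & (t_cancer <= cens)
            outcome = np.where(tie, np.asarray(latent_names, object)[nearest], outcome)
            t_first = np.where(tie, t_cancer, t_first)

    censored = t_first > cens
    outcome = np.where(censored, CENSORED, outcome)
    time = np.where(censored, cens, t_first)
    time = np.maximum(time, MIN_TIME_MONTHS)
    return time, outcome


def apply_observation_scheme(
    latent: Mapping[str, float], config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, str]:
    """Resolve one patient's latent times into (observed time, outcome code).

    The observed time is the earliest latent time, administratively censored;
    a cancer latent time within one day of the death latent time resolves to
    the cancer.  Times are floored at half a day so log-time is defined.
    """
    if not latent:
        raise ValueError("at least one latent time is required")
    names = list(latent)
    times = np.asarray([[latent[k]] for k in names], float)
    if rng is None:
        rng = np.random.default_rng(0)
    cens = _censoring_time(config, rng, 1)
    time, outcome = _resolve_observation(names, times, cens)
    return float(time[0]), str(outcome[0])


def generate_cohort(config: GeneratorConfig, truth: TrueModel) -> pd.DataFrame:
    """Generate ``config.n_patients`` patient records; fully reproducible
    from ``config.seed``.

    Reference-group patients have every symptom indicator zero; symptomatic
    patients have exactly one (two under the multi-symptom extension).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    sex = np.where(rng.random(n) < config.prop_female, FEMALE, MALE)
    smoker = (rng.random(n) < config.prop_ever_smoker).astype(int)
    age = config.age_distribution.sample(n, rng)
    symptomatic = rng.random(n) >= config.prop_reference

    X = np.zeros((n, N_SYMPTOMS), dtype=int)
    for s in SEXES:
        mask = symptomatic & (sex == s)
        k = int(mask.sum())
        if k:
            X[np.flatnonzero(mask), rng.choice(N_SYMPTOMS, size=k, p=config.symptom_probs(s))] = 1
    if config.prop_multi_symptom > 0:
        extra = symptomatic & (rng.random(n) < config.prop_multi_symptom)
        for i in np.flatnonzero(extra):
            p = config.symptom_probs(str(sex[i]))
            p = p.copy()
            p[X[i] == 1] = 0.0
            p = p / p.sum()
            X[i, rng.choice(N_SYMPTOMS, p=p)] = 1

    time = np.empty(n)
    outcome = np.empty(n, dtype=object)
    cens = _censoring_time(config, rng, n)
    for s in SEXES:
        idx = np.flatnonzero(sex == s)
        if idx.size == 0:
            continue
        names = list(truth.causes[s])
        latent = np.empty((len(names), idx.size))
        for j, name in enumerate(names):
            e = rng.exponential(size=idx.size)
            latent[j] = truth.causes[s][name].inverse_cumulative_hazard(
                e, age[idx], smoker[idx], X[idx]
            )
        time[idx], outcome[idx] = _resolve_observation(names, latent, cens[idx])

    df = pd.DataFrame({
        "patient_id": [f"p{i:07d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "ever_smoker": smoker,
        **{sname: X[:, j] for j, sname in enumerate(SYMPTOMS)},
        "time_months": time,
        "outcome": outcome,
    }, columns=list(COHORT_COLUMNS))

    if config.prop_additional_symptom_30d > 0:
        days = np.full(n, np.nan)
        extra = symptomatic & (rng.random(n) < config.prop_additional_symptom_30d)
        # consultation must precede the first event / censoring
        limit_days = np.minimum(30.0, time * DAYS_PER_MONTH)
        extra &= limit_days > 1.0
        k = int(extra.sum())
        if k:
            days[extra] = rng.uniform(1.0, limit_days[extra])
        df[ADDITIONAL_SYMPTOM_COLUMN] = days

    return validate_cohort(df, strict=True)
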