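"""Parametric cause-specific hazards on the log cumulative hazard scale.

A single cause's model is

    ln H(t | x) = eta(u, x)
                = s0(u) + b_age' a(age) + b_smk * smk + sum_s (b_s + g_s * u) x_s,

with ``u = ln t`` (t in months), ``s0`` a restricted cubic spline (or a
plain linear function of ``u``, the Weibull special case), ``a(age)`` an age
spline basis, and each symptom indicator ``x_s`` carrying a main log hazard
ratio ``b_s`` (its value at t = 1 month) plus a log-time interaction ``g_s``
that lets the symptom effect decay over follow-up.

The same class backs the synthetic generator's ground truth and the
predictions of fitted models, so simulation and estimation share one
parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .spline_basis import SplineSpec, rcs_basis, rcs_derivative
from .vocab import FEMALE_ONLY_SYMPTOMS, MALE, N_SYMPTOMS, SEXES, SYMPTOMS

__all__ = [
    "CovariatePattern",
    "ParametricCauseHazard",
    "constant_hazard",
    "weibull_hazard",
]

#: Reference age (years) for the linear age parameterization used by
#: ground-truth presets: the log hazard is linear in (age - 60) / 10.
AGE_CENTER = 60.0
AGE_SCALE = 10.0

_U_LO = -30.0
_U_HI = 30.0


@dataclass(frozen=True)
class CovariatePattern:
    """An (age, sex, smoking, symptom-vector) profile at which risk is predicted."""

    age: float
    sex: str
    ever_smoker: int
    symptoms: tuple[int, ...] = field(default_factory=lambda: (0,) * N_SYMPTOMS)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex code {self.sex!r}")
        if not 30.0 <= self.age <= 99.0:
            raise ValueError(f"age {self.age} outside the supported range [30, 99]")
        if self.ever_smoker not in (0, 1):
            raise ValueError("ever_smoker must be 0 or 1")
        symptoms = tuple(int(v) for v in self.symptoms)
        if len(symptoms) != N_SYMPTOMS or any(v not in (0, 1) for v in symptoms):
            raise ValueError(f"symptoms must be a {N_SYMPTOMS}-vector of 0/1")
        if self.sex == MALE:
            for s in FEMALE_ONLY_SYMPTOMS:
                if symptoms[SYMPTOMS.index(s)]:
                    raise ValueError(f"symptom {s!r} is not recorded for men")
        object.__setattr__(self, "symptoms", symptoms)

    @classmethod
    def with_symptom(
        cls, age: float, sex: str, ever_smoker: int, symptom: str | None
    ) -> "CovariatePattern":
        """Build a pattern with a single index symptom (or none, for the
        reference group)."""
        vec = [0] * N_SYMPTOMS
        if symptom is not None:
            if symptom not in SYMPTOMS:
                raise KeyError(f"unknown symptom {symptom!r}")
            vec[SYMPTOMS.index(symptom)] = 1
        return cls(age=age, sex=sex, ever_smoker=ever_smoker, symptoms=tuple(vec))

    @property
    def symptom_array(self) -> NDArray:
        return np.asarray(self.symptoms, dtype=float)


@dataclass
class ParametricCauseHazard:
    """One cause-specific hazard model (ground truth or fitted point estimate).

    ``baseline_spec=None`` means the baseline is linear in log time
    (``baseline_coefs = [intercept, slope]``, the Weibull case); otherwise
    ``baseline_coefs`` holds the intercept followed by the spline basis
    coefficients.  ``age_spec=None`` with a single ``age_coefs`` entry means
    a log hazard linear in ``(age - 60) / 10``; an empty ``age_coefs`` means
    no age effect.
    """

    outcome: str
    sex: str
    baseline_coefs: NDArray
    baseline_spec: SplineSpec | None = None
    age_spec: SplineSpec | None = None
    age_coefs: NDArray = field(default_factory=lambda: np.zeros(0))
    smoking_lhr: float = 0.0
    symptom_lhr: NDArray = field(default_factory=lambda: np.zeros(N_SYMPTOMS))
    symptom_tve: NDArray = field(default_factory=lambda: np.zeros(N_SYMPTOMS))

    def __post_init__(self) -> None:
        self.baseline_coefs = np.atleast_1d(np.asarray(self.baseline_coefs, float))
        self.age_coefs = np.atleast_1d(np.asarray(self.age_coefs, float)).reshape(-1)
        self.symptom_lhr = np.asarray(self.symptom_lhr, float)
        self.symptom_tve = np.asarray(self.symptom_tve, float)
        nb = 1 if self.baseline_spec is None else self.baseline_spec.n_basis
        if self.baseline_coefs.shape != (1 + nb,):
            raise ValueError(
                f"baseline_coefs must have length {1 + nb}, got {self.baseline_coefs.shape}"
            )
        if self.age_spec is not None and self.age_coefs.shape != (self.age_spec.n_basis,):
            raise ValueError("age_coefs length must match the age spline basis")
        if self.symptom_lhr.shape != (N_SYMPTOMS,) or self.symptom_tve.shape != (N_SYMPTOMS,):
            raise ValueError(f"symptom effect vectors must have length {N_SYMPTOMS}")

    # ---- linear-predictor pieces -------------------------------------------------

    def _baseline_eta(self, u: NDArray) -> NDArray:
        c = self.baseline_coefs
        if self.baseline_spec is None:
            return c[0] + c[1] * u
        return c[0] + rcs_basis(u, self.baseline_spec) @ c[1:]

    def _baseline_deta(self, u: NDArray) -> NDArray:
        c = self.baseline_coefs
        if self.baseline_spec is None:
            return np.broadcast_to(np.asarray(c[1]), np.shape(u)).copy()
        return rcs_derivative(u, self.baseline_spec) @ c[1:]

    def covariate_offset(
        self, age: ArrayLike, ever_smoker: ArrayLike, symptoms: ArrayLike
    ) -> NDArray:
        """Time-constant part of eta: age + smoking + symptom main effects."""
        age = np.asarray(age, float)
        smk = np.asarray(ever_smoker, float)
        X = np.asarray(symptoms, float)
        if self.age_spec is not None:
            off = rcs_basis(age, self.age_spec) @ self.age_coefs
        elif self.age_coefs.size == 1:
            off = self.age_coefs[0] * (age - AGE_CENTER) / AGE_SCALE
        else:
            off = np.zeros(np.shape(age))
        return off + self.smoking_lhr * smk + X @ self.symptom_lhr

    def tve_slope(self, symptoms: ArrayLike) -> NDArray:
        """Symptom-driven addition to d(eta)/du."""
        return np.asarray(symptoms, float) @ self.symptom_tve

    # ---- hazard functions --------------------------------------------------------

    def eta(self, t, age, ever_smoker, symptoms) -> NDArray:
        u = np.log(np.asarray(t, float))
        c = self.covariate_offset(age, ever_smoker, symptoms)
        g = self.tve_slope(symptoms)
        return self._baseline_eta(u) + c + g * u

    def cumulative_hazard(self, t, age, ever_smoker, symptoms) -> NDArray:
        return np.exp(self.eta(t, age, ever_smoker, symptoms))

    def hazard(self, t, age, ever_smoker, symptoms) -> NDArray:
        t = np.asarray(t, float)
        u = np.log(t)
        H = self.cumulative_hazard(t, age, ever_smoker, symptoms)
        dsdu = self._baseline_deta(u) + self.tve_slope(symptoms)
        return H * dsdu / t

    def cumulative_hazard_at(self, pattern: CovariatePattern, t) -> NDArray:
        return self.cumulative_hazard(t, pattern.age, pattern.ever_smoker, pattern.symptom_array)

    def hazard_at(self, pattern: CovariatePattern, t) -> NDArray:
        return self.hazard(t, pattern.age, pattern.ever_smoker, pattern.symptom_array)

    # ---- inversion ---------------------------------------------------------------

    def inverse_cumulative_hazard(
        self, e: ArrayLike, age: ArrayLike, ever_smoker: ArrayLike, symptoms: ArrayLike,
        tol: float = 1e-9,
    ) -> NDArray:
        """Solve ``H(t | x) = e`` for ``t`` (months), elementwise.

        Works on the monotone log-time scale by bisection; draws whose
        solution lies beyond ``exp(30)`` months are returned as ``inf``
        (they can never be observed under any realistic censoring).
        """
        e = np.asarray(e, float)
        if np.any(e <= 0.0):
            raise ValueError("cumulative hazard draws must be positive")
        target = np.log(e) - self.covariate_offset(age, ever_smoker, symptoms)
        target = np.broadcast_to(target, e.shape).astype(float)
        g = np.broadcast_to(self.tve_slope(symptoms), e.shape).astype(float)

        def f(u: NDArray) -> NDArray:
            return self._baseline_eta(u) + g * u - target

        f_lo = f(np.full_like(target, _U_LO))
        f_hi = f(np.full_like(target, _U_HI))
        if np.any(f_hi <= f_lo):
            raise ArithmeticError(
                f"eta is non-increasing in log time for outcome {self.outcome!r}; "
                "the cumulative hazard cannot be inverted"
            )
        lo = np.full_like(target, _U_LO)
        hi = np.full_like(target, _U_HI)
        never = f_hi < 0.0  # event beyond exp(30) months
        n_iter = int(np.ceil(np.log2((_U_HI - _U_LO) / tol)))
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            high = f(mid) >= 0.0
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
        t = np.exp(0.5 * (lo + hi))
        return np.where(never, np.inf, t)

    # ---- serialization -----------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "sex": self.sex,
            "baseline_coefs": self.baseline_coefs.tolist(),
            "baseline_spec": None if self.baseline_spec is None else self.baseline_spec.to_dict(),
            "age_spec": None if self.age_spec is None else self.age_spec.to_dict(),
            "age_coefs": self.age_coefs.tolist(),
            "smoking_lhr": float(self.smoking_lhr),
            "symptom_lhr": self.symptom_lhr.tolist(),
            "symptom_tve": self.symptom_tve.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricCauseHazard":
        return cls(
            outcome=d["outcome"],
            sex=d["sex"],
            baseline_coefs=np.asarray(d["baseline_coefs"], float),
            baseline_spec=None if d.get("baseline_spec") is None else SplineSpec.from_dict(d["baseline_spec"]),
            age_spec=None if d.get("age_spec") is None else SplineSpec.from_dict(d["age_spec"]),
            age_coefs=np.asarray(d.get("age_coefs", []), float),
            smoking_lhr=float(d.get("smoking_lhr", 0.0)),
            symptom_lhr=np.asarray(d.get("symptom_lhr", np.zeros(N_SYMPTOMS)), float),
            symptom_tve=np.asarray(d.get("symptom_tve", np.zeros(N_SYMPTOMS)), float),
        )


def constant_hazard(rate: float, outcome: str = "event", sex: str = "F") -> ParametricCauseHazard:
    """Constant hazard ``rate`` per month: H(t) = rate * t (exact, no splines)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return ParametricCauseHazard(
        outcome=outcome, sex=sex, baseline_coefs=np.array([np.log(rate), 1.0])
    )


def weibull_hazard(
    scale: float, shape: float, outcome: str = "event", sex: str = "F"
) -> ParametricCauseHazard:
    """Weibull cumulative hazard ``H(t) = (scale * t) ** shape``."""
    if scale <= 0 or shape <= 0:
        raise ValueError("scale and shape must be positive")
    return ParametricCauseHazard(
        outcome=outcome, sex=sex,
        baseline_coefs=np.array([shape * np.log(scale), shape]),
    )
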