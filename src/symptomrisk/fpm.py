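"""Cause-specific flexible parametric (Royston–Parmar) survival models.

One model is fitted per sex x outcome by maximum likelihood.  On the log
cumulative hazard scale, with ``u = ln t`` (t in months),

    eta_i = s0(u_i) + b_age' a(age_i) + b_smk smk_i + sum_s (b_s + g_s u_i) x_is,

where ``s0`` is a restricted cubic spline in log time (3 df by default) and
each index symptom has a main effect ``b_s`` — its log hazard ratio at
t = 1 month — plus a log-time interaction ``g_s`` that lets the effect decay
over follow-up.  The right-censored log likelihood is

    l = sum_i [ delta_i (ln(d eta/d u |_i) - ln t_i + eta_i) - exp(eta_i) ],

which is concave in the coefficients wherever ``d eta/d u > 0`` at the event
times (the hazard-positivity region), so a damped Newton iteration from the
exponential-model start converges globally.  Standard errors come from the
inverse observed information at the optimum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from .cohort_io import DesignData, build_design_matrix, load_model_file, save_model_file
from .hazards import CovariatePattern, ParametricCauseHazard
from .spline_basis import SplineSpec, knots_from_quantiles, rcs_basis, rcs_derivative
from .vocab import FEMALE_ONLY_SYMPTOMS, MALE, N_SYMPTOMS, SYMPTOMS, outcomes_for_sex

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FPMFit",
    "InsufficientEventsError",
    "ConvergenceError",
    "log_likelihood",
    "fit_cause_specific",
    "cumulative_hazard",
    "hazard",
    "hr_at_time",
    "hr_at_time_ci",
]

#: Percentiles used for the 6-knot age spline (boundary knots pulled in from
#: the extremes so sparse tails do not dictate the flexible region).
AGE_KNOT_PERCENTILES = (5.0, 21.0, 37.0, 63.0, 79.0, 95.0)


class InsufficientEventsError(RuntimeError):
    """Refusal to fit: fewer target events than ``FitOptions.min_events``."""


class ConvergenceError(RuntimeError):
    """The Newton iteration failed; ``.trace`` carries the log-likelihood path."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def default_symptoms(sex: str) -> tuple[str, ...]:
    if sex == MALE:
        return tuple(s for s in SYMPTOMS if s not in FEMALE_ONLY_SYMPTOMS)
    return SYMPTOMS


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one cause-specific model (sex x target outcome).

    ``baseline_spec``/``age_spec`` may be left unresolved (None); the fit
    places baseline knots on the quantiles of the target outcome's log event
    times and age knots on cohort age percentiles.
    """

    sex: str
    outcome: str
    baseline_df: int = 3
    baseline_spec: SplineSpec | None = None
    include_age: bool = True
    age_spec: SplineSpec | None = None
    include_smoking: bool = True
    symptoms: tuple[str, ...] | None = None
    tve_symptoms: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.outcome not in outcomes_for_sex(self.sex).event_codes:
            raise ValueError(f"outcome {self.outcome!r} is not modelled for sex {self.sex!r}")
        symptoms = self.symptoms if self.symptoms is not None else default_symptoms(self.sex)
        symptoms = tuple(symptoms)
        unknown = [s for s in symptoms if s not in SYMPTOMS]
        if unknown:
            raise ValueError(f"unknown symptoms {unknown}")
        tve = self.tve_symptoms if self.tve_symptoms is not None else symptoms
        tve = tuple(tve)
        if not set(tve) <= set(symptoms):
            raise ValueError("time-varying symptoms must be a subset of the symptom list")
        object.__setattr__(self, "symptoms", symptoms)
        object.__setattr__(self, "tve_symptoms", tve)
        if self.baseline_df < 1:
            raise ValueError("baseline_df must be >= 1")

    def param_names(self) -> list[str]:
        names = ["baseline_intercept"]
        names += [f"baseline_rcs{j + 1}" for j in range(self.baseline_df)]
        if self.include_age:
            names += [f"age_rcs{j + 1}" for j in range(len(AGE_KNOT_PERCENTILES) - 1)]
        if self.include_smoking:
            names.append("ever_smoker")
        names += list(self.symptoms)
        names += [f"{s}:log_time" for s in self.tve_symptoms]
        return names

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "outcome": self.outcome,
            "baseline_df": self.baseline_df,
            "baseline_spec": None if self.baseline_spec is None else self.baseline_spec.to_dict(),
            "include_age": self.include_age,
            "age_spec": None if self.age_spec is None else self.age_spec.to_dict(),
            "include_smoking": self.include_smoking,
            "symptoms": list(self.symptoms),
            "tve_symptoms": list(self.tve_symptoms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            sex=d["sex"],
            outcome=d["outcome"],
            baseline_df=d.get("baseline_df", 3),
            baseline_spec=None if d.get("baseline_spec") is None else SplineSpec.from_dict(d["baseline_spec"]),
            include_age=d.get("include_age", True),
            age_spec=None if d.get("age_spec") is None else SplineSpec.from_dict(d["age_spec"]),
            include_smoking=d.get("include_smoking", True),
            symptoms=tuple(d["symptoms"]),
            tve_symptoms=tuple(d["tve_symptoms"]),
        )

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class FitOptions:
    min_events: int = 10
    max_iter: int = 200
    gtol: float = 1e-6          # max-norm of the score at convergence
    ltol: float = 1e-10         # relative log-likelihood change at convergence
    constrain_zero: tuple[str, ...] = ()   # parameter names held at exactly 0


# ---------------------------------------------------------------------------
# Likelihood machinery


class _Workspace:
    """Expanded design for the likelihood: eta = X theta, d(eta)/du = Z theta."""

    def __init__(self, data: DesignData, spec: ModelSpec):
        if spec.baseline_spec is None:
            raise ValueError("spec.baseline_spec must be resolved before evaluation")
        t = np.asarray(data.time, float)
        if np.any(t <= 0):
            raise ValueError("all follow-up times must be positive")
        u = np.log(t)
        n = t.size
        b = rcs_basis(u, spec.baseline_spec)
        db = rcs_derivative(u, spec.baseline_spec)
        nb = b.shape[1]
        if nb != spec.baseline_df:
            raise ValueError("baseline spline df does not match the spec")
        tve_idx = [spec.symptoms.index(s) for s in spec.tve_symptoms]
        X_tve = data.symptoms[:, tve_idx]
        blocks_X = [np.ones((n, 1)), b, data.age_basis, data.smoker, data.symptoms,
                    X_tve * u[:, None]]
        blocks_Z = [np.zeros((n, 1)), db, np.zeros_like(data.age_basis),
                    np.zeros_like(data.smoker), np.zeros_like(data.symptoms), X_tve]
        self.X = np.concatenate(blocks_X, axis=1)
        self.Z = np.concatenate(blocks_Z, axis=1)
        self.u = u
        self.logt = u
        self.delta = np.asarray(data.event, float)
        self.event_mask = self.delta > 0
        self.n, self.p = self.X.shape
        names = spec.param_names()
        if len(names) != self.p:
            raise ValueError("parameter names out of sync with the design")
        self.names = names

    def loglik(self, theta: NDArray) -> float:
        value, _ = self.loglik_grad(theta)
        return value

    def loglik_grad(self, theta: NDArray) -> tuple[float, NDArray]:
        theta = np.asarray(theta, float)
        if theta.shape != (self.p,):
            raise ValueError(f"expected {self.p} parameters, got {theta.shape}")
        eta = self.X @ theta
        ds = self.Z @ theta
        if np.any(ds[self.event_mask] <= 0.0):
            # hazard would be negative at an observed event time: outside the
            # model's feasible region — signal with a large finite penalty
            return -1e12, np.zeros(self.p)
        eta = np.clip(eta, -700.0, 700.0)
        expeta = np.exp(eta)
        d = self.delta
        with np.errstate(divide="ignore"):
            ll = float(np.sum(d * (np.log(np.where(d > 0, ds, 1.0)) - self.logt + eta))
                       - np.sum(expeta))
        grad = (d / np.where(d > 0, ds, 1.0) * d) @ self.Z + (d - expeta) @ self.X
        return ll, grad

    def hessian(self, theta: NDArray) -> NDArray:
        eta = np.clip(self.X @ theta, -700.0, 700.0)
        ds = self.Z @ theta
        d = self.delta
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            w_z = np.where(d > 0, d / np.maximum(ds, 1e-150) ** 2, 0.0)
        w_x = np.exp(eta)
        return -(self.Z.T * w_z) @ self.Z - (self.X.T * w_x) @ self.X


def log_likelihood(params: NDArray, data: DesignData, spec: ModelSpec) -> tuple[float, NDArray]:
    """Right-censored log likelihood and its analytic gradient.

    Returns a large negative sentinel (with a zero gradient) when the hazard
    is non-positive at any observed event time.
    """
    return _Workspace(data, spec).loglik_grad(np.asarray(params, float))


def _resolve_spec(df, spec: ModelSpec) -> ModelSpec:
    """Fill in data-driven knots: baseline on the target outcome's log event
    times, age on cohort age percentiles."""
    if spec.baseline_spec is None:
        ev = df.loc[df["outcome"] == spec.outcome, "time_months"].to_numpy(float)
        if ev.size == 0:
            raise InsufficientEventsError(
                f"no {spec.outcome!r} events to place baseline knots on")
        bl = knots_from_quantiles(np.log(ev), m=spec.baseline_df + 1, scale_label="log_time")
        spec = replace(spec, baseline_spec=bl)
    if spec.include_age and spec.age_spec is None:
        ages = df["age"].to_numpy(float)
        knots = np.percentile(ages, AGE_KNOT_PERCENTILES)
        if np.unique(knots).size < len(knots):
            raise ValueError("cohort ages too concentrated to place 6 distinct age knots")
        spec = replace(spec, age_spec=SplineSpec(knots=tuple(knots), scale_label="age"))
    return spec


def _initial_theta(ws: _Workspace) -> NDArray:
    """Exponential-model start: hazard = events / person-time, unit log-time
    slope, all other coefficients zero.  Always inside the feasible region."""
    theta = np.zeros(ws.p)
    rate = max(float(ws.delta.sum()), 0.5) / float(np.sum(np.exp(ws.u)))
    theta[0] = np.log(rate)
    theta[1] = 1.0
    return theta


def _newton(ws: _Workspace, free: NDArray, options: FitOptions) -> tuple[NDArray, list[float], bool, int]:
    theta = _initial_theta(ws)
    theta[~free] = 0.0
    ll, grad = ws.loglik_grad(theta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, options.max_iter + 1):
        g = grad[free]
        H = ws.hessian(theta)[np.ix_(free, free)]
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.trace(-H) / len(g)
            step = np.linalg.solve(-H + ridge * np.eye(len(g)), g)
        if not np.all(np.isfinite(step)) or g @ step <= 0:
            step = g / max(1.0, np.linalg.norm(g))  # steepest-ascent fallback
        # damped line search keeps iterates feasible and monotone
        alpha = 1.0
        for _ in range(60):
            trial = theta.copy()
            trial[free] += alpha * step
            ll_new, grad_new = ws.loglik_grad(trial)
            if ll_new > ll - 1e-12:
                break
            alpha *= 0.5
        else:
            break
        rel_change = abs(ll_new - ll) / (abs(ll) + 1.0)
        theta, grad = trial, grad_new
        ll = ll_new
        trace.append(ll)
        if np.max(np.abs(grad[free])) < options.gtol or rel_change < options.ltol:
            converged = True
            break
    return theta, trace, converged, it


@dataclass
class FPMFit:
    """A fitted cause-specific model: coefficients, covariance and metadata."""

    spec: ModelSpec
    params: NDArray
    param_names: list[str]
    cov: NDArray
    loglik: float
    converged: bool
    n: int
    n_events: int
    n_iter: int = 0

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def _slice(self, names: list[str]) -> NDArray:
        idx = [self.param_names.index(n) for n in names]
        return self.params[idx]

    def to_hazard_model(self) -> ParametricCauseHazard:
        """Point-estimate predictor in the shared hazard parameterization."""
        spec = self.spec
        nb = spec.baseline_df
        baseline = self.params[: 1 + nb]
        if spec.include_age:
            n_age = len(AGE_KNOT_PERCENTILES) - 1
            age_coefs = self._slice([f"age_rcs{j + 1}" for j in range(n_age)])
            age_spec = spec.age_spec
        else:
            age_coefs, age_spec = np.zeros(0), None
        smoking = self.coef("ever_smoker") if spec.include_smoking else 0.0
        lhr = np.zeros(N_SYMPTOMS)
        tve = np.zeros(N_SYMPTOMS)
        for s in spec.symptoms:
            lhr[SYMPTOMS.index(s)] = self.coef(s)
        for s in spec.tve_symptoms:
            tve[SYMPTOMS.index(s)] = self.coef(f"{s}:log_time")
        return ParametricCauseHazard(
            outcome=spec.outcome, sex=spec.sex,
            baseline_coefs=baseline, baseline_spec=spec.baseline_spec,
            age_spec=age_spec, age_coefs=age_coefs,
            smoking_lhr=smoking, symptom_lhr=lhr, symptom_tve=tve,
        )

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "spec_hash": self.spec.content_hash(),
            "param_names": self.param_names,
            "params": np.asarray(self.params).tolist(),
            "cov": np.asarray(self.cov).tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n": self.n,
            "n_events": self.n_events,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPMFit":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            params=np.asarray(d["params"], float),
            param_names=list(d["param_names"]),
            cov=np.asarray(d["cov"], float),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n=int(d["n"]),
            n_events=int(d["n_events"]),
            n_iter=int(d.get("n_iter", 0)),
        )

    def save(self, path: str | Path) -> None:
        save_model_file(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "FPMFit":
        return cls.from_dict(load_model_file(path))


def fit_cause_specific(df, spec: ModelSpec, options: FitOptions | None = None) -> FPMFit:
    """Maximum-likelihood fit of one cause-specific model.

    ``df`` is a validated single-sex cohort frame, already censored at the
    fitting horizon.  Baseline and age knots are placed from the data when
    the spec leaves them unresolved.
    """
    options = options or FitOptions()
    n_events = int((df["outcome"] == spec.outcome).sum())
    if n_events < options.min_events:
        raise InsufficientEventsError(
            f"{spec.sex}/{spec.outcome}: {n_events} events < min_events={options.min_events}"
        )
    spec = _resolve_spec(df, spec)
    data = build_design_matrix(df, spec)
    ws = _Workspace(data, spec)
    free = np.array([name not in options.constrain_zero for name in ws.names])
    theta, trace, converged, n_iter = _newton(ws, free, options)
    if not converged:
        raise ConvergenceError(
            f"{spec.sex}/{spec.outcome}: Newton iteration did not converge "
            f"in {options.max_iter} steps (final loglik {trace[-1]:.6f})",
            trace,
        )
    # covariance from the observed information on the free parameters
    H = ws.hessian(theta)[np.ix_(free, free)]
    cov_free = np.linalg.inv(-H)
    cov = np.zeros((ws.p, ws.p))
    cov[np.ix_(free, free)] = cov_free
    # post-fit check: fitted hazard positive at every observed event time
    ds = ws.Z @ theta
    if np.any(ds[ws.event_mask] <= 0):
        raise ConvergenceError(
            f"{spec.sex}/{spec.outcome}: fitted hazard non-positive at an event time",
            trace,
        )
    ll, _ = ws.loglik_grad(theta)
    return FPMFit(
        spec=spec, params=theta, param_names=ws.names, cov=cov,
        loglik=ll, converged=converged, n=ws.n, n_events=n_events, n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Predictions


def cumulative_hazard(fit: FPMFit, pattern: CovariatePattern, t) -> NDArray:
    """H(t | pattern) = exp(eta); t in months, strictly positive."""
    if np.any(np.asarray(t, float) <= 0):
        raise ValueError("t must be positive")
    return fit.to_hazard_model().cumulative_hazard_at(pattern, t)


def hazard(fit: FPMFit, pattern: CovariatePattern, t) -> NDArray:
    """Instantaneous cause-specific hazard h(t | pattern) = H * d(eta)/du / t."""
    if np.any(np.asarray(t, float) <= 0):
        raise ValueError("t must be positive")
    return fit.to_hazard_model().hazard_at(pattern, t)


def _symptom_coeffs(fit_or_coeffs, symptom: str) -> tuple[float, float]:
    if isinstance(fit_or_coeffs, FPMFit):
        if symptom not in fit_or_coeffs.spec.symptoms:
            raise KeyError(f"symptom {symptom!r} not in the fitted model")
        beta = fit_or_coeffs.coef(symptom)
        gamma = (fit_or_coeffs.coef(f"{symptom}:log_time")
                 if symptom in fit_or_coeffs.spec.tve_symptoms else 0.0)
        return beta, gamma
    beta, gamma = fit_or_coeffs
    return float(beta), float(gamma)


def hr_at_time(fit_or_coeffs, symptom: str, t: float) -> float:
    """Time-varying hazard ratio HR(t) = exp(beta_s + gamma_s ln t).

    At t = 1 month this is exp(beta_s), the reporting convention for symptom
    effects; with a negative gamma_s the ratio decays over follow-up.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    beta, gamma = _symptom_coeffs(fit_or_coeffs, symptom)
    return float(np.exp(beta + gamma * np.log(t)))


def hr_at_time_ci(fit: FPMFit, symptom: str, t: float, level: float = 0.95) -> tuple[float, float, float]:
    """HR(t) with a Wald interval via the delta method on the log scale."""
    from scipy.stats import norm

    beta, gamma = _symptom_coeffs(fit, symptom)
    u = np.log(t)
    i = fit.param_names.index(symptom)
    lhr = beta + gamma * u
    var = fit.cov[i, i]
    if symptom in fit.spec.tve_symptoms:
        j = fit.param_names.index(f"{symptom}:log_time")
        var = var + u * u * fit.cov[j, j] + 2 * u * fit.cov[i, j]
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(np.exp(lhr)), float(np.exp(lhr - half)), float(np.exp(lhr + half))
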