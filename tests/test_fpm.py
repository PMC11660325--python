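"""Flexible parametric model: likelihood oracles, fitting, predictions and
time-varying hazard ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize

from symptomrisk.cohort_io import build_design_matrix, validate_cohort, COHORT_COLUMNS
from symptomrisk.fpm import (
    FitOptions,
    InsufficientEventsError,
    ModelSpec,
    _resolve_spec,
    cumulative_hazard,
    fit_cause_specific,
    hazard,
    hr_at_time,
    log_likelihood,
)
from symptomrisk.hazards import CovariatePattern
from symptomrisk.spline_basis import SplineSpec
from symptomrisk.synthetic_cohort import generate_cohort
from symptomrisk.vocab import SYMPTOMS

from conftest import (
    RECOVERY_SYMPTOM,
    TRUE_BETA,
    TRUE_GAMMA,
    TRUE_SMOKING,
    make_recovery_config,
    make_recovery_truth,
)


def _tiny_frame(times, outcomes):
    rows = []
    for i, (t, o) in enumerate(zip(times, outcomes)):
        row = {c: 0 for c in SYMPTOMS}
        row.update({"patient_id": f"p{i}", "age": 60.0, "sex": "F",
                    "ever_smoker": 0, "time_months": t, "outcome": o})
        rows.append(row)
    return validate_cohort(pd.DataFrame(rows, columns=list(COHORT_COLUMNS)))


NOCOV = dict(include_age=False, include_smoking=False, symptoms=(), tve_symptoms=())
BASE_SPEC = SplineSpec(knots=(np.log(0.5), np.log(2.0), np.log(6.0), np.log(18.0)))


def weibull_loglik(log_lam, p, times, events):
    """Closed-form Weibull right-censored log likelihood, H(t) = (lam t)^p."""
    lam = np.exp(log_lam)
    H = (lam * times) ** p
    h = p * lam * (lam * times) ** (p - 1)
    return float(np.sum(events * np.log(h) - H))


class TestLogLikelihood:
    def test_linear_spline_equals_weibull_closed_form(self):
        # three hand records: two events, one censored
        times = np.array([2.0, 5.0, 10.0])
        events = np.array([1.0, 1.0, 0.0])
        df = _tiny_frame(times, ["lung", "lung", "censored"])
        spec = ModelSpec(sex="F", outcome="lung", baseline_spec=BASE_SPEC, **NOCOV)
        data = build_design_matrix(df, spec)
        log_lam, p = np.log(0.08), 1.4
        params = np.array([p * log_lam, p, 0.0, 0.0])  # nonlinear terms off
        value, _ = log_likelihood(params, data, spec)
        assert value == pytest.approx(weibull_loglik(log_lam, p, times, events), abs=1e-10)

    def test_censoring_only_reduces_to_minus_sum_cumhaz(self):
        times = np.array([3.0, 7.0])
        df = _tiny_frame(times, ["censored", "censored"])
        spec = ModelSpec(sex="F", outcome="lung", baseline_spec=BASE_SPEC, **NOCOV)
        data = build_design_matrix(df, spec)
        params = np.array([-3.0, 1.2, 0.05, -0.02])
        value, _ = log_likelihood(params, data, spec)
        from symptomrisk.spline_basis import rcs_basis
        eta = params[0] + rcs_basis(np.log(times), BASE_SPEC) @ params[1:]
        assert value == pytest.approx(-np.sum(np.exp(eta)))

    def test_gradient_matches_finite_differences(self, recovery_cohort):
        df = recovery_cohort.head(2000)
        spec = _resolve_spec(df, ModelSpec(sex="F", outcome="lung",
                                           symptoms=(RECOVERY_SYMPTOM,)))
        data = build_design_matrix(df, spec)
        rng = np.random.default_rng(1)
        params = np.zeros(len(spec.param_names()))
        params[0], params[1] = -5.0, 1.0
        params += 0.01 * rng.standard_normal(params.size)
        value, grad = log_likelihood(params, data, spec)
        fd = np.empty_like(grad)
        h = 1e-6
        for i in range(params.size):
            up, dn = params.copy(), params.copy()
            up[i] += h
            dn[i] -= h
            fd[i] = (log_likelihood(up, data, spec)[0] - log_likelihood(dn, data, spec)[0]) / (2 * h)
        scale = np.maximum(np.abs(grad), 1.0)
        assert np.max(np.abs(grad - fd) / scale) < 1e-5

    def test_negative_hazard_region_returns_sentinel(self):
        df = _tiny_frame([2.0], ["lung"])
        spec = ModelSpec(sex="F", outcome="lung", baseline_spec=BASE_SPEC, **NOCOV)
        data = build_design_matrix(df, spec)
        value, grad = log_likelihood(np.array([-3.0, -1.0, 0.0, 0.0]), data, spec)
        assert value < -1e11
        assert np.all(grad == 0)

    def test_likelihood_invariant_under_record_permutation(self, recovery_cohort):
        df = recovery_cohort.head(3000)
        spec = _resolve_spec(df, ModelSpec(sex="F", outcome="lung",
                                           symptoms=(RECOVERY_SYMPTOM,)))
        params = np.zeros(len(spec.param_names()))
        params[0], params[1] = -5.0, 1.0
        a = log_likelihood(params, build_design_matrix(df, spec), spec)[0]
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        b = log_likelihood(params, build_design_matrix(shuffled, spec), spec)[0]
        assert a == pytest.approx(b, rel=1e-12)


@pytest.fixture(scope="module")
def recovery_fit(recovery_cohort):
    spec = ModelSpec(sex="F", outcome="lung", symptoms=(RECOVERY_SYMPTOM,))
    return fit_cause_specific(recovery_cohort, spec)


class TestFitting:
    def test_recovers_symptom_effect_within_3se(self, recovery_fit):
        fit = recovery_fit
        assert abs(fit.coef(RECOVERY_SYMPTOM) - TRUE_BETA) < 3 * fit.se(RECOVERY_SYMPTOM)
        name = f"{RECOVERY_SYMPTOM}:log_time"
        assert abs(fit.coef(name) - TRUE_GAMMA) < 3 * fit.se(name)
        assert abs(fit.coef("ever_smoker") - TRUE_SMOKING) < 3 * fit.se("ever_smoker")

    def test_exponential_baseline_reproduced_within_5pct(self):
        lam = 0.02
        from symptomrisk.synthetic_cohort import GeneratorConfig, AgeDistribution, TrueModel
        from symptomrisk.hazards import constant_hazard
        truth = TrueModel(causes={"F": {"lung": constant_hazard(lam, "lung", "F")}})
        cfg = GeneratorConfig(
            n_patients=40_000, prop_reference=1.0, symptom_mix={"haemoptysis": 1.0},
            prop_female=1.0, prop_ever_smoker=0.0,
            age_distribution=AgeDistribution(name="fixed", age=60.0), seed=21,
        )
        cohort = generate_cohort(cfg, truth)
        fit = fit_cause_specific(cohort, ModelSpec(sex="F", outcome="lung", **NOCOV))
        pattern = CovariatePattern(age=60.0, sex="F", ever_smoker=0)
        for t in (1.0, 3.0, 6.0, 12.0):
            assert cumulative_hazard(fit, pattern, t) == pytest.approx(lam * t, rel=0.05)

    def test_duplicated_data_same_estimates_halved_variance(self, recovery_cohort):
        df = recovery_cohort.head(8000)
        doubled = pd.concat([df, df], ignore_index=True)
        # resolve the data-driven knots once so both fits share the same
        # basis (quantile interpolation shifts slightly under duplication)
        spec = _resolve_spec(df, ModelSpec(sex="F", outcome="lung",
                                           symptoms=(RECOVERY_SYMPTOM,)))
        fit1 = fit_cause_specific(df, spec)
        fit2 = fit_cause_specific(doubled, spec)
        assert np.allclose(fit1.params, fit2.params, atol=1e-5)
        ratio = fit1.se(RECOVERY_SYMPTOM) / fit2.se(RECOVERY_SYMPTOM)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.01)

    def test_too_few_events_refused(self):
        df = _tiny_frame([1.0, 2.0, 3.0], ["lung", "censored", "censored"])
        with pytest.raises(InsufficientEventsError, match="events"):
            fit_cause_specific(df, ModelSpec(sex="F", outcome="lung", **NOCOV))

    def test_weibull_limit_matches_direct_weibull_fit(self, recovery_cohort):
        """Constraining the nonlinear spline terms to zero reproduces a
        directly coded Weibull maximum likelihood to 1e-6."""
        df = recovery_cohort.head(20_000)
        df = df[(df[RECOVERY_SYMPTOM] == 0) & (df["ever_smoker"] == 0)]
        spec = ModelSpec(sex="F", outcome="lung", **NOCOV)
        fit = fit_cause_specific(
            df, spec,
            FitOptions(constrain_zero=("baseline_rcs2", "baseline_rcs3"), gtol=1e-8),
        )
        times = df["time_months"].to_numpy()
        events = (df["outcome"] == "lung").to_numpy(float)
        res = minimize(
            lambda x: -weibull_loglik(x[0], np.exp(x[1]), times, events),
            x0=np.array([np.log(0.01), 0.0]), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)


class TestPredictions:
    def test_cumulative_hazard_vanishes_at_zero(self, recovery_fit):
        pattern = CovariatePattern(age=60.0, sex="F", ever_smoker=0)
        assert cumulative_hazard(recovery_fit, pattern, 1e-10) < 1e-6

    def test_hazard_integrates_to_cumulative_hazard(self, recovery_fit):
        pattern = CovariatePattern.with_symptom(70.0, "F", 1, RECOVERY_SYMPTOM)
        t = 9.0
        integral, _ = quad(lambda s: float(hazard(recovery_fit, pattern, s)),
                           1e-9, t, limit=200)
        assert integral == pytest.approx(
            float(cumulative_hazard(recovery_fit, pattern, t)), rel=1e-4)

    def test_proportional_hazards_limit_without_tve(self, recovery_cohort):
        spec = ModelSpec(sex="F", outcome="lung", symptoms=(RECOVERY_SYMPTOM,),
                         tve_symptoms=())
        fit = fit_cause_specific(recovery_cohort, spec)
        with_s = CovariatePattern.with_symptom(60.0, "F", 0, RECOVERY_SYMPTOM)
        without = CovariatePattern(age=60.0, sex="F", ever_smoker=0)
        ratios = [
            float(cumulative_hazard(fit, with_s, t) / cumulative_hazard(fit, without, t))
            for t in (1.0, 4.0, 12.0)
        ]
        assert np.allclose(ratios, np.exp(fit.coef(RECOVERY_SYMPTOM)), rtol=1e-9)

    def test_nonpositive_time_rejected(self, recovery_fit):
        pattern = CovariatePattern(age=60.0, sex="F", ever_smoker=0)
        with pytest.raises(ValueError):
            cumulative_hazard(recovery_fit, pattern, 0.0)


class TestHrAtTime:
    def test_main_effect_at_one_month(self):
        assert hr_at_time((np.log(17.1), np.log(0.7)), "haemoptysis", 1.0) == pytest.approx(17.1)

    def test_decayed_value_at_12_months(self):
        hr = hr_at_time((np.log(17.1), np.log(0.7)), "haemoptysis", 12.0)
        assert hr == pytest.approx(17.1 * 0.7 ** np.log(12.0), rel=1e-12)
        assert hr == pytest.approx(7.05, abs=0.01)

    def test_constant_when_gamma_zero(self):
        for t in (0.5, 1.0, 6.0, 12.0):
            assert hr_at_time((np.log(3.0), 0.0), "dyspnoea", t) == pytest.approx(3.0)

    def test_unknown_symptom_rejected(self, recovery_cohort):
        spec = ModelSpec(sex="F", outcome="lung", symptoms=(RECOVERY_SYMPTOM,))
        fit = fit_cause_specific(recovery_cohort, spec)
        with pytest.raises(KeyError):
            hr_at_time(fit, "jaundice", 1.0)
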