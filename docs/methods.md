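# Methods

This document specifies the statistical model, the synthetic-cohort
generator, the numerical choices, and the limitations of the package.
Notation: t is time in months since the index consultation, u = ln t.

## 1. Study design being emulated

Patients aged 30–99 enter a cohort at their first primary-care consultation
for one of 15 studied symptoms, or as a dynamically sampled reference group
with none of them.  The first subsequent event within 18 months is
classified as one of nine cancer-group diagnoses or non-cancer death;
everything else is administratively censored at 18 months.  Models are
fitted on the full 18-month window; all risk predictions, crude estimates
and summaries are reported at a 12-month horizon.  Sexes are modelled
separately: women have nine cancer groups (including breast and
gynaecological), men eight (including prostate); post-menopausal bleeding
applies to women only.

Same-day convention: when a non-cancer death and a cancer occur within one
day (1/30.44 months) of each other, the event is attributed to the cancer,
mirroring death-certificate diagnoses.  Event times are floored at half a
day so log time is always defined.

## 2. Restricted cubic splines

For knots k_1 < … < k_m, the basis is v_1(u) = u and, for j = 2…m−1,

    v_j(u) = (u−k_j)₊³ − λ_j (u−k_1)₊³ − (1−λ_j)(u−k_m)₊³,
    λ_j = (k_m−k_j)/(k_m−k_1)

which is linear beyond the boundary knots and C² everywhere
(`spline_basis.py`).  Baseline-time knots are placed at the min, max and
equally spaced internal quantiles of the log event times of the target
cause (3 degrees of freedom → 4 knots).  Age knots sit at the 5th, 21st,
37th, 63rd, 79th and 95th percentiles of the cohort's ages (6 knots → 5
basis columns); the age signal in cancer incidence is strong enough to
warrant the extra flexibility.

## 3. The cause-specific model

For each sex × cause, on the log cumulative-hazard scale:

    η(u, x) = s0(u) + b_age' a(age) + b_smk · smk + Σ_s (β_s + γ_s u) x_s
    ln H(t | x) = η(ln t, x)

The γ_s u interactions make each symptom's hazard ratio decay (or grow)
geometrically in log time: HR_s(t) = exp(β_s + γ_s ln t), so β_s is the log
hazard ratio at exactly one month, the reporting convention throughout.

### Likelihood and optimization

With right censoring, δ_i the event indicator, and both η and ∂η/∂u linear
in the parameter vector θ (η = Xθ, ∂η/∂u = Zθ):

    ℓ(θ) = Σ δ_i [ln(Zθ)_i − ln t_i + (Xθ)_i] − Σ exp((Xθ)_i)

This is concave on the feasible region {(Zθ)_i > 0 at every event}, so
Newton's method with an analytic gradient and Hessian

    ∇ℓ = Z'(δ/Zθ) + X'(δ − e^{Xθ})
    ∇²ℓ = −Z' diag(δ/(Zθ)²) Z − X' diag(e^{Xθ}) X

converges in a handful of damped steps from an exponential-model start; the
line search halves the step until it stays feasible and increases ℓ.  The
analytic Hessian is exact here (no numerical differentiation is needed) and
doubles as the observed information: the covariance matrix is its negative
inverse at the optimum.  Fits refuse to run below a minimum event count
(default 10) rather than return unstable estimates, and individual
parameters can be constrained to zero (used for the Weibull-limit check).
With very sparse strata the unpenalized MLE can still diverge (complete
separation: a symptom column with zero events of the target cause gets
β̂ → −∞ with a huge standard error); this is reported honestly rather than
shrunk.

### Weibull special case

A linear baseline spline (s0(u) = c_0 + c_1 u) is exactly a Weibull model
with H(t) = (λt)^p, p = c_1, ln λ = c_0/c_1; the test suite verifies that
the constrained spline fit matches a directly coded Weibull maximum
likelihood to 10⁻⁶.

## 4. Cumulative incidence under competing risks

Given the fitted cause-specific cumulative hazards, 12-month cumulative
incidence at a covariate pattern is estimated by latent-failure-time
simulation: draw e_j ~ Exp(1) independently per cause, invert t_j =
H_j⁻¹(e_j) (vectorized bisection on u ∈ [−30, 30] to |Δu| < 10⁻⁹), and take
the first event before the horizon.  CIF_j(t) is the fraction of draws with
cause j by t; the Monte-Carlo standard error is √(p(1−p)/n).  For constant
hazards the closed form

    CIF_j(t) = λ_j/Σλ · (1 − e^{−Σλ t})

serves as an exact oracle — λ = (0.1, 0.3), t = 12 gives (0.2479, 0.7438).

The non-parametric cross-check is a hand-rolled Aalen–Johansen estimator:
with all-cause Kaplan–Meier survival S, CIF_j jumps by S(t⁻) d_j/n at each
event time, tied competing events share the same risk set, and censoring at
an event time is processed after the event.  It is written directly (rather
than wrapping a library) so that tie conventions are explicit and exact on
hand fixtures; a library implementation is used as a cross-check in the
tests on tie-free data.

## 5. Threshold ages and summaries

For each sex × smoking × symptom profile the threshold scan walks a 5-year
age grid (30, 35, …, 95) and reports the youngest age at which the
simulated 12-month risk of any cancer (the sum of the mutually exclusive
group CIFs) and of each group reaches 3%.  CIFs are rounded to 4 decimal
places before comparison so Monte-Carlo wobble at an exact boundary cannot
flip a verdict, and each grid age reuses the same seed and draw count.
An invariant is enforced on every table: the any-cancer age never exceeds
any group-specific age.

Descriptive summaries count, per stratum, cancers within 12 months and
deaths within 12 months without a preceding cancer diagnosis, with row
percentages and Wilson score intervals.  Wilson is used because it
reproduces the published intervals exactly after 1-dp rounding (52/449 →
11.6% (8.9%, 14.9%); 480/10 360 → 4.6% (4.2%, 5.1%)), is well behaved at
small counts, and has a lower limit of exactly 0 at k = 0.

## 6. The synthetic generator

Real national primary-care records are confidential, so the generator
produces structurally faithful synthetic cohorts:

- covariates: sex, ever-smoker status, age (fixed / uniform / banded
  distributions), and one index symptom per patient (mutually exclusive
  classes; extensions add multi-symptom-at-index and
  additional-symptom-within-30-days records);
- outcomes: per-cause latent times drawn by inverting the true cumulative
  hazards, first event kept, administrative censoring at 18 months, the
  same-day tie rule and half-day floor applied as in §1.

The `table1` preset reproduces the published cohort's margins (48.5%
reference group, the 15 symptom sub-cohort sizes, 54.3% women, 63.8%
ever-smokers, the 10-year age-band mix) and calibrates each cause's
baseline intercept so the marginal 12-month risks match the published rates
(≈2.2–2.3% cancer, ≈1.8% non-cancer death).  The calibration is a
deterministic fixed-point on numerically integrated risks (CIF_j = ∫S dH_j
over a discretized covariate grid) — no simulation in the loop, so the
preset is reproducible bit for bit.  Symptom, smoking and age effects use
representative published magnitudes (e.g. haemoptysis → lung HR 17.1 at one
month, decaying by 0.7 per log month; jaundice → upper-GI HR 110).

What the generator does **not** emulate: consultation and referral
processes, symptom recurrence, registration churn, deprivation and
ethnicity structure, regional case-mix, or correlated comorbidity — it is a
test harness for the estimators, not a disease model.

## 7. Key defaults

| Parameter | Default | Rationale |
|---|---|---|
| baseline spline df | 3 | enough shape for 18-month hazards without overfitting rare causes |
| age spline knots | 6 at fixed percentiles | strong, nonlinear age effects on incidence |
| fitting horizon | 18 months | full observation window |
| reporting horizon | 12 months | the clinically quoted risk window |
| CIF draws | 100 000 | MC s.e. ≤ 0.16 percentage points |
| threshold draws | 50 000 per grid age | grid verdicts stable after 4-dp rounding |
| minimum events per fit | 10 | below this the MLE is not trustworthy |
| risk threshold | 3% | urgent-referral guidance level |
| age grid | 30–95 by 5 | ages considered in 5-year intervals |

## 8. Limitations

- Threshold ages from the calibrated synthetic preset characterize the
  method, not the real population; real-data headline estimates are not
  reproducible without the confidential source records.
- Cause-specific models assume independent latent times given covariates
  (the standard competing-risks identification caveat).
- No penalization: sparse symptom × cause strata can separate (see §3);
  users should check event counts per stratum, which the pipeline logs.
- One index symptom per patient in the core generator; the multi-symptom
  extension adds labels but not interaction effects in the truth.
- Calendar time, deprivation and ethnicity are out of scope.
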