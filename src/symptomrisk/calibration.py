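"""Published cohort marginals and the calibrated ground-truth preset.

The counts below are the published summary of the national primary-care
symptom cohort (1 622 419 patients, 2007-2017) whose structure the synthetic
generator emulates: the reference-group share, the 15 symptomatic sub-cohort
sizes, the sex, smoking and grouped-age margins, and the 12-month cancer and
non-cancer death counts.  They serve two purposes: they parameterize the
default generator configuration, and the descriptive-summary module
recomputes row percentages and Wilson intervals from them as an arithmetic
cross-check.

``table1_truth`` builds a ground-truth model whose 12-month outcome risks
are calibrated — by deterministic numerical integration over the generator's
covariate distribution, not by simulation — to the published cohort-wide
rates (2.3% cancer, 1.8% non-cancer death).  Symptom and smoking effects are
set to representative published magnitudes (e.g. haemoptysis -> lung cancer
hazard ratio 17 at one month, decaying by a factor 0.7 per log month).
"""

from __future__ import annotations

import numpy as np

from .hazards import ParametricCauseHazard
from .synthetic_cohort import AgeDistribution, GeneratorConfig, TrueModel
from .vocab import FEMALE, MALE, N_SYMPTOMS, NONCANCER_DEATH, SYMPTOMS, outcomes_for_sex

__all__ = [
    "TOTAL_PATIENTS",
    "SYMPTOM_TABLE",
    "MULTI_SYMPTOM_TABLE",
    "table1_config",
    "table1_truth",
    "expected_cif",
]

TOTAL_PATIENTS = 1_622_419
TOTAL_CANCERS_12M = 36_802
TOTAL_DEATHS_12M = 28_867
REFERENCE_N = 786_424
FEMALE_N = 880_888
MALE_N = 741_531
EVER_SMOKER_N = 1_035_780

#: Per index-symptom row: cohort N, cancers within 12 months, deaths within
#: 12 months without a preceding cancer diagnosis.  ``None`` keys the
#: reference group.
SYMPTOM_TABLE: dict[str | None, tuple[int, int, int]] = {
    None: (786_424, 7_536, 12_520),
    "abdominal_pain": (236_226, 5_675, 2_203),
    "abdominal_bloating": (23_228, 660, 272),
    "rectal_bleeding": (49_273, 1_896, 875),
    "change_in_bowel_habit": (17_629, 1_091, 165),
    "dyspepsia": (110_312, 2_178, 976),
    "dysphagia": (15_291, 1_053, 1_181),
    "jaundice": (1_898, 468, 221),
    "dyspnoea": (142_431, 4_015, 6_308),
    "haemoptysis": (5_984, 417, 147),
    "haematuria": (26_051, 2_791, 601),
    "fatigue": (143_719, 2_476, 2_247),
    "night_sweats": (7_857, 137, 31),
    "weight_loss": (20_163, 1_291, 1_196),
    "breast_lump": (38_623, 4_814, 90),
    "post_menopausal_bleeding": (8_252, 799, 50),
}

#: Grouped ages (10-year bands) and cohort counts.
AGE_BAND_TABLE: tuple[tuple[float, float, int], ...] = (
    (30.0, 40.0, 395_413),
    (40.0, 50.0, 350_133),
    (50.0, 60.0, 295_316),
    (60.0, 70.0, 259_039),
    (70.0, 80.0, 185_854),
    (80.0, 90.0, 111_933),
    (90.0, 99.0, 24_731),
)

#: Multiple-symptom summary: per class (single index symptom / multiple at
#: index / additional studied symptom within 30 days): patients, cancers
#: within 12 months of index.
MULTI_SYMPTOM_TABLE: dict[str, tuple[int, int]] = {
    "single": (825_635, 28_834),
    "multi_at_index": (10_360, 480),
    "additional_within_30d": (21_167, 1_429),
}
SYMPTOMATIC_N = 835_995


def table1_config(n_patients: int, seed: int = 0, **overrides) -> GeneratorConfig:
    """Generator configuration matching the published cohort margins."""
    counts = np.array([SYMPTOM_TABLE[s][0] for s in SYMPTOMS], float)
    mix = dict(zip(SYMPTOMS, counts / counts.sum()))
    band_n = np.array([b[2] for b in AGE_BAND_TABLE], float)
    ages = AgeDistribution(
        name="banded_uniform",
        bands=tuple((b[0], b[1]) for b in AGE_BAND_TABLE),
        weights=tuple(band_n / band_n.sum()),
    )
    params = dict(
        n_patients=n_patients,
        prop_reference=REFERENCE_N / TOTAL_PATIENTS,
        symptom_mix=mix,
        prop_female=FEMALE_N / TOTAL_PATIENTS,
        prop_ever_smoker=EVER_SMOKER_N / TOTAL_PATIENTS,
        age_distribution=ages,
        admin_censor_months=18.0,
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


# ---------------------------------------------------------------------------
# Ground-truth effects
#
# (hazard ratio at 1 month, multiplicative decay per log month) for notable
# symptom -> outcome pairs; pairs not listed have no effect.  Magnitudes
# follow the published cause-specific estimates where available.

_SYMPTOM_EFFECTS: dict[tuple[str, str], tuple[float, float]] = {
    ("haemoptysis", "lung"): (17.1, 0.7),
    ("haemoptysis", "haematological"): (2.8, 1.0),
    ("haemoptysis", NONCANCER_DEATH): (1.5, 1.0),
    ("dyspnoea", "lung"): (2.6, 0.85),
    ("dyspnoea", "haematological"): (1.7, 1.0),
    ("dyspnoea", NONCANCER_DEATH): (2.5, 0.85),
    ("rectal_bleeding", "lower_gi"): (17.4, 0.75),
    ("rectal_bleeding", NONCANCER_DEATH): (0.8, 1.0),
    ("change_in_bowel_habit", "lower_gi"): (21.5, 0.75),
    ("change_in_bowel_habit", NONCANCER_DEATH): (0.9, 1.0),
    ("jaundice", "upper_gi"): (110.0, 0.6),
    ("jaundice", "haematological"): (3.0, 1.0),
    ("jaundice", NONCANCER_DEATH): (8.0, 0.7),
    ("dysphagia", "upper_gi"): (16.4, 0.75),
    ("dysphagia", NONCANCER_DEATH): (5.0, 0.85),
    ("dyspepsia", "upper_gi"): (4.0, 0.85),
    ("dyspepsia", NONCANCER_DEATH): (0.9, 1.0),
    ("abdominal_pain", "lower_gi"): (4.0, 0.85),
    ("abdominal_pain", "upper_gi"): (4.0, 0.85),
    ("abdominal_pain", "urological"): (1.5, 1.0),
    ("abdominal_pain", "gynaecological"): (2.0, 1.0),
    ("abdominal_pain", NONCANCER_DEATH): (0.8, 1.0),
    ("abdominal_bloating", "lower_gi"): (3.0, 0.9),
    ("abdominal_bloating", "upper_gi"): (4.0, 0.85),
    ("abdominal_bloating", "gynaecological"): (4.8, 0.8),
    ("abdominal_bloating", NONCANCER_DEATH): (0.85, 1.0),
    ("haematuria", "urological"): (30.0, 0.7),
    ("haematuria", "prostate"): (4.0, 0.85),
    ("haematuria", NONCANCER_DEATH): (0.9, 1.0),
    ("fatigue", "haematological"): (2.0, 0.9),
    ("fatigue", "other_cancer"): (1.5, 1.0),
    ("fatigue", NONCANCER_DEATH): (1.2, 1.0),
    ("night_sweats", "haematological"): (3.5, 0.85),
    ("night_sweats", "other_cancer"): (1.5, 1.0),
    ("night_sweats", NONCANCER_DEATH): (0.8, 1.0),
    ("weight_loss", "upper_gi"): (4.0, 0.8),
    ("weight_loss", "lower_gi"): (3.0, 0.85),
    ("weight_loss", "lung"): (3.0, 0.85),
    ("weight_loss", "haematological"): (2.5, 0.9),
    ("weight_loss", "other_cancer"): (2.0, 1.0),
    ("weight_loss", NONCANCER_DEATH): (4.0, 0.8),
    ("breast_lump", "breast"): (60.0, 0.65),
    ("breast_lump", NONCANCER_DEATH): (0.5, 1.0),
    ("post_menopausal_bleeding", "gynaecological"): (25.0, 0.7),
    ("post_menopausal_bleeding", NONCANCER_DEATH): (0.7, 1.0),
}

#: Smoking hazard ratios per outcome (shared across sexes).
_SMOKING_HR: dict[str, float] = {
    "lung": 4.4, "upper_gi": 1.4, "urological": 1.4,
    NONCANCER_DEATH: 1.6,
}
_SMOKING_HR_DEFAULT = 1.15

#: Log hazard ratio of age per decade (on (age - 60) / 10).
_AGE_LHR: dict[str, float] = {
    "breast": np.log(1.3),
    "gynaecological": np.log(1.5),
    "prostate": np.log(2.5),
    NONCANCER_DEATH: np.log(2.8),
}
_AGE_LHR_DEFAULT = np.log(1.9)

#: Calibration targets: 12-month first-event risk of each outcome within one
#: sex's cohort (fractions; cancers sum to ~2.2% for women, ~2.3% for men).
_TARGET_12M: dict[str, dict[str, float]] = {
    FEMALE: {
        "breast": 0.0055, "gynaecological": 0.0020, "lung": 0.0030,
        "upper_gi": 0.0015, "lower_gi": 0.0025, "urological": 0.0010,
        "haematological": 0.0020, "other_cancer": 0.0045,
        NONCANCER_DEATH: 0.0180,
    },
    MALE: {
        "lung": 0.0040, "upper_gi": 0.0020, "lower_gi": 0.0030,
        "urological": 0.0025, "prostate": 0.0050,
        "haematological": 0.0025, "other_cancer": 0.0040,
        NONCANCER_DEATH: 0.0180,
    },
}


def _covariate_cells(config: GeneratorConfig, sex: str):
    """Discretize the generator's covariate distribution for one sex into
    weighted cells (age x smoking x symptom class)."""
    dist = config.age_distribution
    if dist.name == "fixed":
        ages, age_w = np.array([dist.age]), np.array([1.0])
    elif dist.name == "uniform":
        edges = np.linspace(dist.lo, dist.hi, 21)
        ages = 0.5 * (edges[:-1] + edges[1:])
        age_w = np.full(20, 1 / 20)
    else:
        ages_list, w_list = [], []
        for (lo, hi), w in zip(dist.bands, dist.weights):
            k = max(int(round(hi - lo)), 1)
            edges = np.linspace(lo, hi, k + 1)
            ages_list.append(0.5 * (edges[:-1] + edges[1:]))
            w_list.append(np.full(k, w / k))
        ages, age_w = np.concatenate(ages_list), np.concatenate(w_list)

    sym_probs = config.symptom_probs(sex)
    classes: list[tuple[np.ndarray, float]] = [(np.zeros(N_SYMPTOMS), config.prop_reference)]
    for j in range(N_SYMPTOMS):
        if sym_probs[j] > 0:
            x = np.zeros(N_SYMPTOMS)
            x[j] = 1.0
            classes.append((x, (1 - config.prop_reference) * sym_probs[j]))

    cells_age, cells_smk, cells_X, cells_w = [], [], [], []
    for smk, p_smk in ((0, 1 - config.prop_ever_smoker), (1, config.prop_ever_smoker)):
        for x, p_x in classes:
            cells_age.append(ages)
            cells_smk.append(np.full(ages.size, smk))
            cells_X.append(np.tile(x, (ages.size, 1)))
            cells_w.append(age_w * p_smk * p_x)
    return (np.concatenate(cells_age), np.concatenate(cells_smk),
            np.vstack(cells_X), np.concatenate(cells_w))


def expected_cif(
    truth: TrueModel, config: GeneratorConfig, horizon: float = 12.0,
    n_steps: int = 240,
) -> dict[str, dict[str, float]]:
    """Exact (up to quadrature) 12-month first-event risk of each outcome
    within each sex's cohort, marginalized over the generator's covariate
    distribution: CIF_j = integral of S(t) dH_j(t)."""
    out: dict[str, dict[str, float]] = {}
    t_grid = np.linspace(0.0, horizon, n_steps + 1)
    t_mid = np.maximum(0.5 * (t_grid[:-1] + t_grid[1:]), 1e-6)
    for sex, models in truth.causes.items():
        age, smk, X, w = _covariate_cells(config, sex)
        H = {}   # cumulative hazard at grid points, per cause: (cells, T+1)
        for outcome, m in models.items():
            Ht = np.array([
                m.cumulative_hazard(max(t, 1e-12), age, smk, X) if t > 0 else np.zeros(age.size)
                for t in t_grid
            ]).T
            H[outcome] = Ht
        H_all = sum(H.values())
        S_mid = np.exp(-0.5 * (H_all[:, :-1] + H_all[:, 1:]))
        out[sex] = {}
        for outcome in models:
            dH = np.diff(H[outcome], axis=1)
            cif_cells = np.sum(S_mid * dH, axis=1)
            out[sex][outcome] = float(np.sum(w * cif_cells))
    return out


def _base_truth() -> TrueModel:
    causes: dict[str, dict[str, ParametricCauseHazard]] = {}
    for sex in (FEMALE, MALE):
        causes[sex] = {}
        for outcome in outcomes_for_sex(sex).event_codes:
            lhr = np.zeros(N_SYMPTOMS)
            tve = np.zeros(N_SYMPTOMS)
            for j, s in enumerate(SYMPTOMS):
                eff = _SYMPTOM_EFFECTS.get((s, outcome))
                if eff is not None:
                    lhr[j] = np.log(eff[0])
                    tve[j] = np.log(eff[1])
            causes[sex][outcome] = ParametricCauseHazard(
                outcome=outcome, sex=sex,
                # constant baseline hazard placeholder; intercept calibrated below
                baseline_coefs=np.array([np.log(1e-4), 1.0]),
                age_coefs=np.array([_AGE_LHR.get(outcome, _AGE_LHR_DEFAULT)]),
                smoking_lhr=np.log(_SMOKING_HR.get(outcome, _SMOKING_HR_DEFAULT)),
                symptom_lhr=lhr, symptom_tve=tve,
            )
    return TrueModel(causes=causes)


def table1_truth(config: GeneratorConfig | None = None, n_rounds: int = 4) -> TrueModel:
    """Ground truth calibrated so each outcome's marginal 12-month risk under
    ``config`` matches the published cohort rates.

    The calibration is a deterministic fixed-point on the baseline
    intercepts: each round rescales every cause's hazard by the ratio of its
    target to its current integrated 12-month risk.
    """
    config = config or table1_config(n_patients=1000)
    truth = _base_truth()
    for _ in range(n_rounds):
        current = expected_cif(truth, config)
        for sex, models in truth.causes.items():
            for outcome, m in models.items():
                target = _TARGET_12M[sex][outcome]
                cur = current[sex][outcome]
                if cur > 0:
                    m.baseline_coefs[0] += np.log(target / cur)
    return truth
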