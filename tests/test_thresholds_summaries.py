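"""Threshold ages, descriptive summaries and Wilson intervals."""

import numpy as np
import pandas as pd
import pytest

from symptomrisk.calibration import (
    MULTI_SYMPTOM_TABLE,
    SYMPTOM_TABLE,
    SYMPTOMATIC_N,
    table1_config,
    table1_truth,
)
from symptomrisk.cohort_io import COHORT_COLUMNS, validate_cohort
from symptomrisk.hazards import ParametricCauseHazard, constant_hazard
from symptomrisk.synthetic_cohort import generate_cohort
from symptomrisk.thresholds_summaries import (
    ThresholdResult,
    ThresholdTable,
    age_at_threshold,
    multi_symptom_summary,
    proportion_with_ci,
    summarize_cohort,
)
from symptomrisk.vocab import SYMPTOMS, outcomes_for_sex


class TestWilsonIntervals:
    @pytest.mark.parametrize(
        "k,n,expect",
        [
            (52, 449, (11.6, 8.9, 14.9)),
            (480, 10_360, (4.6, 4.2, 5.1)),
            (28_834, 825_635, (3.5, 3.5, 3.5)),
            (1_429, 21_167, (6.8, 6.4, 7.1)),
        ],
    )
    def test_reproduces_published_rows_at_1dp(self, k, n, expect):
        p, lo, hi = proportion_with_ci(k, n)
        assert (round(100 * p, 1), round(100 * lo, 1), round(100 * hi, 1)) == expect

    def test_zero_events_boundary(self):
        p, lo, hi = proportion_with_ci(0, 10)
        assert p == 0.0
        assert lo == 0.0
        assert 0 < hi < 1

    def test_interval_contains_estimate_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 1000))
            k = int(rng.integers(0, n + 1))
            p, lo, hi = proportion_with_ci(k, n)
            assert 0.0 <= lo <= p <= hi <= 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_with_ci(5, 4)


class TestPublishedCountArithmetic:
    def test_symptom_row_percentages(self):
        n, cancers, _ = SYMPTOM_TABLE["jaundice"]
        assert round(100 * cancers / n, 1) == 24.7
        n, cancers, _ = SYMPTOM_TABLE["haematuria"]
        assert round(100 * cancers / n, 1) == 10.7

    def test_multi_symptom_fractions(self):
        n, _ = MULTI_SYMPTOM_TABLE["multi_at_index"]
        assert round(100 * n / SYMPTOMATIC_N, 1) == 1.2
        n, _ = MULTI_SYMPTOM_TABLE["additional_within_30d"]
        assert round(100 * n / SYMPTOMATIC_N, 1) == 2.5


def _toy_cohort():
    rows = []
    specs = [
        ("F", "jaundice", 3.0, "upper_gi"),
        ("F", "jaundice", 6.0, "noncancer_death"),
        ("F", "jaundice", 18.0, "censored"),
        ("F", "jaundice", 14.0, "upper_gi"),     # after 12m: not counted
        ("M", None, 2.0, "lung"),
        ("M", None, 18.0, "censored"),
    ]
    for i, (sex, symptom, t, outcome) in enumerate(specs):
        row = {c: 0 for c in SYMPTOMS}
        if symptom:
            row[symptom] = 1
        row.update({"patient_id": f"p{i}", "age": 64.0, "sex": sex,
                    "ever_smoker": i % 2, "time_months": t, "outcome": outcome})
        rows.append(row)
    return validate_cohort(pd.DataFrame(rows, columns=list(COHORT_COLUMNS)))


class TestSummarizeCohort:
    def test_counts_and_row_percentages(self):
        summary = summarize_cohort(_toy_cohort())
        row = summary.row("symptom", "jaundice")
        assert row["n"] == 4
        assert row["cancers_12m"] == 1          # the 14-month cancer is outside 12m
        assert row["deaths_12m_no_cancer"] == 1
        assert row["cancer_row_pct"] == pytest.approx(25.0)
        ref = summary.row("symptom", "reference")
        assert ref["n"] == 2
        assert ref["cancers_12m"] == 1

    def test_empty_stratum_has_undefined_percentage(self):
        summary = summarize_cohort(_toy_cohort())
        row = summary.row("symptom", "haemoptysis")
        assert row["n"] == 0
        assert np.isnan(row["cancer_row_pct"])

    def test_partitioning_sections_sum_to_total(self):
        summary = summarize_cohort(_toy_cohort())
        sexes = summary.table[summary.table["section"] == "sex"]
        assert sexes["n"].sum() == summary.total_n


class TestMultiSymptomSummary:
    def test_no_multi_symptom_patients_yield_empty_classes(self):
        out = multi_symptom_summary(_toy_cohort())
        any_multi = out[(out["index_symptom"] == "any") & (out["class"] == "multi_at_index")]
        assert int(any_multi["patients"].iloc[0]) == 0
        assert np.isnan(any_multi["pct"].iloc[0])

    def test_generator_extension_produces_configured_fractions(self):
        cfg = table1_config(n_patients=30_000, seed=31,
                            prop_multi_symptom=0.05,
                            prop_additional_symptom_30d=0.05)
        cohort = generate_cohort(cfg, table1_truth(cfg))
        out = multi_symptom_summary(cohort)
        sub = out[out["index_symptom"] == "any"].set_index("class")
        n_sym = sub["patients"].sum()
        frac_multi = sub.loc["multi_at_index", "patients"] / n_sym
        assert frac_multi == pytest.approx(0.05, abs=0.01)
        assert sub.loc["additional_within_30d", "patients"] > 0


def _scaled(model: ParametricCauseHazard, factor: float) -> ParametricCauseHazard:
    d = model.to_dict()
    d["baseline_coefs"][0] += np.log(factor)
    return ParametricCauseHazard.from_dict(d)


@pytest.fixture(scope="module")
def truth_models():
    return table1_truth().causes["M"]


class TestAgeAtThreshold:
    GRID = (50.0, 65.0, 80.0)

    def test_saturating_risk_returns_youngest_grid_age(self):
        fits = {o: constant_hazard(0.05 if o != "noncancer_death" else 0.01, o, "M")
                for o in outcomes_for_sex("M").event_codes}
        res = age_at_threshold(fits, "M", 0, None, age_grid=(30.0, 35.0), n_draws=2000)
        assert res.any_cancer_age == 30.0

    def test_negligible_risk_returns_none(self, truth_models):
        tiny = {o: _scaled(m, 0.01) for o, m in truth_models.items()}
        res = age_at_threshold(tiny, "M", 0, "haemoptysis",
                               age_grid=self.GRID, n_draws=5000)
        assert res.any_cancer_age is None
        assert all(a is None for a in res.group_ages.values())

    def test_scaling_hazards_up_never_raises_threshold_age(self, truth_models):
        base = age_at_threshold(truth_models, "M", 1, "haemoptysis",
                                age_grid=self.GRID, n_draws=20_000, seed=2)
        boosted = {o: (_scaled(m, 3.0) if o != "noncancer_death" else m)
                   for o, m in truth_models.items()}
        up = age_at_threshold(boosted, "M", 1, "haemoptysis",
                              age_grid=self.GRID, n_draws=20_000, seed=2)
        if base.any_cancer_age is not None:
            assert up.any_cancer_age is not None
            assert up.any_cancer_age <= base.any_cancer_age

    def test_any_cancer_age_dominates_group_ages(self, truth_models):
        res = age_at_threshold(truth_models, "M", 1, "haemoptysis",
                               age_grid=self.GRID, n_draws=20_000, seed=2)
        group_ages = [a for a in res.group_ages.values() if a is not None]
        if group_ages:
            assert res.any_cancer_age is not None
            assert res.any_cancer_age <= min(group_ages)

    def test_dominance_violation_rejected_by_table(self):
        bad = ThresholdResult(sex="M", ever_smoker=0, symptom=None, threshold=0.03,
                              any_cancer_age=None, group_ages={"lung": 40.0})
        with pytest.raises(AssertionError, match="dominance"):
            ThresholdTable(rows=[bad])

    def test_missing_cause_rejected(self, truth_models):
        partial = {k: v for k, v in truth_models.items() if k != "lung"}
        with pytest.raises(KeyError, match="lung"):
            age_at_threshold(partial, "M", 0, "haemoptysis", age_grid=self.GRID)
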