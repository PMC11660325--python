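"""Decision-facing outputs: 3%-risk threshold ages and cohort summaries.

UK referral guidance uses a 3% predicted cancer risk as the urgent-referral
threshold.  For each sex x smoking x symptom profile this module finds the
youngest age, on a 5-year grid, at which the modelled 12-month cumulative
incidence of any cancer (and of each cancer group) reaches the threshold.
Descriptive summaries reproduce the published tables' semantics: counts of
cancers and of deaths without a preceding cancer diagnosis within 12 months,
with row percentages and Wilson score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort_io import ADDITIONAL_SYMPTOM_COLUMN, cancer_event_mask, death_event_mask
from .hazards import CovariatePattern
from .multistate_cif import simulate_cif
from .vocab import FEMALE, MALE, SYMPTOMS, outcomes_for_sex

__all__ = [
    "DEFAULT_AGE_GRID",
    "ThresholdResult",
    "ThresholdTable",
    "SummaryTable",
    "age_at_threshold",
    "threshold_table",
    "summarize_cohort",
    "proportion_with_ci",
    "multi_symptom_summary",
]

#: Ages considered in 5-year intervals.
DEFAULT_AGE_GRID: tuple[float, ...] = tuple(float(a) for a in range(30, 100, 5))

#: CIFs are rounded to 4 decimal places before threshold comparison, so a
#: Monte-Carlo wobble at an exact boundary cannot flip the verdict.
_CIF_DECIMALS = 4


@dataclass
class ThresholdResult:
    """Youngest grid age reaching the risk threshold, for one profile."""

    sex: str
    ever_smoker: int
    symptom: str | None
    threshold: float
    any_cancer_age: float | None
    group_ages: dict[str, float | None]


@dataclass
class ThresholdTable:
    """Rows keyed by (sex, smoking, symptom); any-cancer age dominates every
    group-specific age because the group CIFs sum to the any-cancer CIF."""

    rows: list[ThresholdResult]

    def __post_init__(self) -> None:
        for row in self.rows:
            ages = [a for a in row.group_ages.values() if a is not None]
            if ages and (row.any_cancer_age is None or row.any_cancer_age > min(ages)):
                raise AssertionError(
                    f"threshold dominance violated for {row.sex}/{row.ever_smoker}/"
                    f"{row.symptom}: any-cancer {row.any_cancer_age} vs groups {row.group_ages}"
                )

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {
                "sex": row.sex,
                "ever_smoker": row.ever_smoker,
                "symptom": row.symptom if row.symptom is not None else "reference",
                "threshold": row.threshold,
                "any_cancer": row.any_cancer_age,
            }
            rec.update(row.group_ages)
            records.append(rec)
        return pd.DataFrame(records)


def age_at_threshold(
    fits: Mapping[str, object],
    sex: str,
    smoking: int,
    symptom: str | None,
    threshold: float = 0.03,
    horizon: float = 12.0,
    age_grid: Sequence[float] = DEFAULT_AGE_GRID,
    n_draws: int = 50_000,
    seed: int = 0,
) -> ThresholdResult:
    """Youngest grid age at which the simulated 12-month cancer risk reaches
    ``threshold`` (any cancer, and per cancer group).

    Each grid age uses the same number of draws and the same seed, so the
    scan is reproducible and ages differ only through the covariate pattern.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be a fraction in (0, 1)")
    vocab = outcomes_for_sex(sex)
    missing = [o for o in vocab.event_codes if o not in fits]
    if missing:
        raise KeyError(f"missing fitted models for outcomes: {missing}")
    any_age: float | None = None
    group_ages: dict[str, float | None] = {g: None for g in vocab.cancer_groups}
    for age in age_grid:
        pattern = CovariatePattern.with_symptom(age, sex, smoking, symptom)
        table = simulate_cif(
            fits, pattern, n_draws=n_draws, horizon=horizon,
            grid=[horizon], seed=seed,
        )
        total = round(float(table.total_cancer(vocab.cancer_groups)[-1]), _CIF_DECIMALS)
        if any_age is None and total >= threshold:
            any_age = float(age)
        for g in vocab.cancer_groups:
            cif_g = round(float(table.cif[g][-1]), _CIF_DECIMALS)
            if group_ages[g] is None and cif_g >= threshold:
                group_ages[g] = float(age)
    return ThresholdResult(
        sex=sex, ever_smoker=smoking, symptom=symptom,
        threshold=threshold, any_cancer_age=any_age, group_ages=group_ages,
    )


def threshold_table(
    fits_by_sex: Mapping[str, Mapping[str, object]],
    symptoms: Sequence[str | None] | None = None,
    threshold: float = 0.03,
    horizon: float = 12.0,
    age_grid: Sequence[float] = DEFAULT_AGE_GRID,
    n_draws: int = 50_000,
    seed: int = 0,
) -> ThresholdTable:
    """Full threshold-age table over sex x smoking x symptom profiles."""
    if symptoms is None:
        symptoms = [None] + list(SYMPTOMS)
    rows = []
    for sex in (FEMALE, MALE):
        if sex not in fits_by_sex:
            continue
        for symptom in symptoms:
            if symptom == "post_menopausal_bleeding" and sex == MALE:
                continue
            for smoking in (0, 1):
                rows.append(age_at_threshold(
                    fits_by_sex[sex], sex, smoking, symptom,
                    threshold=threshold, horizon=horizon,
                    age_grid=age_grid, n_draws=n_draws, seed=seed,
                ))
    return ThresholdTable(rows=rows)


# ---------------------------------------------------------------------------
# Descriptive summaries


def proportion_with_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float, float]:
    """Binomial proportion with a Wilson score interval.

    The Wilson interval is used because it behaves sensibly at small counts
    and at the boundaries (lower limit exactly 0 when k = 0).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    p = k / n
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    # guard against floating-point noise at the boundaries (e.g. k = 0 can
    # produce a lower limit of ~1e-17 instead of exactly 0)
    return p, float(min(max(lo, 0.0), p)), float(max(min(hi, 1.0), p))


@dataclass
class SummaryTable:
    """Counts and percentages by stratum; percentages recompute from counts."""

    table: pd.DataFrame
    total_n: int

    def __post_init__(self) -> None:
        df = self.table
        for section in df["section"].unique():
            sub = df[df["section"] == section]
            if section != "total" and int(sub["n"].sum()) != self.total_n:
                raise AssertionError(f"section {section!r} counts do not sum to the total")

    def row(self, section: str, stratum: str) -> pd.Series:
        sel = self.table[(self.table["section"] == section) & (self.table["stratum"] == stratum)]
        if len(sel) != 1:
            raise KeyError(f"no unique row for {section}/{stratum}")
        return sel.iloc[0]


def _summary_row(section: str, stratum: str, n_total: int, sub: pd.DataFrame) -> dict:
    n = len(sub)
    cancers = int(cancer_event_mask(sub).sum())
    deaths = int(death_event_mask(sub).sum())
    return {
        "section": section,
        "stratum": stratum,
        "n": n,
        "col_pct": 100.0 * n / n_total if n_total else np.nan,
        "cancers_12m": cancers,
        "cancer_row_pct": 100.0 * cancers / n if n else np.nan,
        "deaths_12m_no_cancer": deaths,
        "death_row_pct": 100.0 * deaths / n if n else np.nan,
    }


def summarize_cohort(df: pd.DataFrame) -> SummaryTable:
    """Cohort summary with the published tables' semantics.

    For every stratum (total, 10-year age band, sex, smoking, index symptom):
    cohort N with column percentage, cancers within 12 months and deaths
    within 12 months without a preceding cancer diagnosis, each with row
    percentages.  A death counts only when non-cancer death is the first
    event; empty strata render with undefined (NaN) percentages.
    """
    n_total = len(df)
    rows = [_summary_row("total", "total", n_total, df)]
    for lo in range(30, 100, 10):
        hi = min(lo + 10, 100)
        sub = df[(df["age"] >= lo) & (df["age"] < hi)]
        rows.append(_summary_row("age_band", f"{lo} to {hi - 1}", n_total, sub))
    for sex, label in ((FEMALE, "female"), (MALE, "male")):
        rows.append(_summary_row("sex", label, n_total, df[df["sex"] == sex]))
    for smk, label in ((0, "never_smoker"), (1, "ever_smoker")):
        rows.append(_summary_row("smoking", label, n_total, df[df["ever_smoker"] == smk]))
    sym = df[list(SYMPTOMS)].to_numpy(int)
    reference = sym.sum(axis=1) == 0
    rows.append(_summary_row("symptom", "reference", n_total, df[reference]))
    for j, s in enumerate(SYMPTOMS):
        rows.append(_summary_row("symptom", s, n_total, df[sym[:, j] == 1]))
    table = pd.DataFrame(rows)
    # symptom strata overlap under the multi-symptom extension; the section
    # total check only applies to the partitioning sections
    partitioning = table["section"].isin(["total", "age_band", "sex", "smoking"])
    summary = SummaryTable(table=table[partitioning].reset_index(drop=True), total_n=n_total)
    summary.table = table
    return summary


def multi_symptom_summary(
    df: pd.DataFrame, window_days: float = 30.0, level: float = 0.95
) -> pd.DataFrame:
    """12-month cancer proportions by multiple-symptom class.

    Symptomatic patients are classified as ``single`` (one index symptom,
    no further studied-symptom consultation within the window),
    ``multi_at_index`` (two or more symptoms on the index date) or
    ``additional_within_30d`` (a further studied symptom within the window,
    before any diagnosis).  Tabulated overall ('any') and per index symptom,
    with Wilson intervals.
    """
    sym = df[list(SYMPTOMS)].to_numpy(int)
    n_sym = sym.sum(axis=1)
    symptomatic = n_sym > 0
    multi = n_sym >= 2
    if ADDITIONAL_SYMPTOM_COLUMN in df.columns:
        extra_days = df[ADDITIONAL_SYMPTOM_COLUMN].to_numpy(float)
        additional = symptomatic & ~multi & (extra_days <= window_days)
    else:
        additional = np.zeros(len(df), bool)
    single = symptomatic & ~multi & ~additional
    cancer = cancer_event_mask(df).to_numpy()

    classes = (("single", single), ("multi_at_index", multi),
               ("additional_within_30d", additional))
    rows = []
    for index_symptom, mask_sym in [("any", symptomatic)] + [
        (s, sym[:, j] == 1) for j, s in enumerate(SYMPTOMS)
    ]:
        for label, mask_class in classes:
            mask = mask_sym & mask_class
            n = int(mask.sum())
            k = int((mask & cancer).sum())
            if n > 0:
                p, lo, hi = proportion_with_ci(k, n, level)
            else:
                p = lo = hi = np.nan
            rows.append({
                "index_symptom": index_symptom, "class": label,
                "patients": n, "cancers_12m": k,
                "pct": 100.0 * p if n else np.nan,
                "ci_lower_pct": 100.0 * lo if n else np.nan,
                "ci_upper_pct": 100.0 * hi if n else np.nan,
            })
    return pd.DataFrame(rows)
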