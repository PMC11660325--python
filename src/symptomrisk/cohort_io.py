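"""Reading, validating and encoding patient-level cohort tables.

A cohort is one row per patient: age at the index consultation, sex,
ever-smoker flag, 15 binary index-symptom indicators (all zero for the
reference group), follow-up time in months and the outcome code of the
first event (a cancer group, non-cancer death, or ``censored``).

Cohorts are carried in memory as validated :class:`pandas.DataFrame` objects
with a fixed column order; :class:`PatientRecord` gives a typed view of a
single row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .vocab import (
    AGE_MAX,
    AGE_MIN,
    CANCER_GROUPS,
    CENSORED,
    FEMALE,
    FEMALE_ONLY_SYMPTOMS,
    MALE,
    OUTCOMES,
    SYMPTOMS,
    outcomes_for_sex,
)

log = logging.getLogger(__name__)

#: Canonical cohort column order.
COHORT_COLUMNS: tuple[str, ...] = (
    ("patient_id", "age", "sex", "ever_smoker") + SYMPTOMS + ("time_months", "outcome")
)

#: Optional extension column: days from index to an additional studied-symptom
#: consultation (blank when none occurred before censoring / diagnosis).
ADDITIONAL_SYMPTOM_COLUMN = "additional_symptom_days"


class CohortValidationError(ValueError):
    """A cohort table violated the schema; the message names the first bad row."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject: covariates at index, follow-up, and first-event outcome."""

    patient_id: str
    age: float
    sex: str
    ever_smoker: int
    symptoms: tuple[int, ...]
    time_months: float
    outcome: str

    @property
    def is_reference(self) -> bool:
        return not any(self.symptoms)


def records(df: pd.DataFrame) -> Iterator[PatientRecord]:
    """Iterate a validated cohort frame as typed records."""
    sym = df[list(SYMPTOMS)].to_numpy(int)
    for i, (_, row) in enumerate(df.iterrows()):
        yield PatientRecord(
            patient_id=str(row["patient_id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            ever_smoker=int(row["ever_smoker"]),
            symptoms=tuple(sym[i]),
            time_months=float(row["time_months"]),
            outcome=str(row["outcome"]),
        )


def _row_problems(df: pd.DataFrame) -> pd.Series:
    """Return a string Series: the first validation problem per row ('' if clean)."""
    n = len(df)
    problem = pd.Series([""] * n, index=df.index)

    def flag(mask: pd.Series, msg: str) -> None:
        fresh = mask & (problem == "")
        problem[fresh] = msg

    flag(~df["sex"].isin([FEMALE, MALE]), "sex must be F or M")
    age = pd.to_numeric(df["age"], errors="coerce")
    flag(age.isna() | (age < AGE_MIN) | (age > AGE_MAX),
         f"age must be in [{AGE_MIN:g}, {AGE_MAX:g}]")
    flag(~df["ever_smoker"].isin([0, 1]), "ever_smoker must be 0 or 1")
    for s in SYMPTOMS:
        flag(~df[s].isin([0, 1]), f"symptom {s} must be 0 or 1")
    t = pd.to_numeric(df["time_months"], errors="coerce")
    flag(t.isna() | (t <= 0.0), "time_months must be a positive number")
    flag(~df["outcome"].isin(OUTCOMES), "unknown outcome code")
    male = df["sex"] == MALE
    flag(male & df["outcome"].isin(["breast", "gynaecological"]),
         "breast/gynaecological outcomes require sex=F")
    flag((df["sex"] == FEMALE) & (df["outcome"] == "prostate"),
         "prostate outcome requires sex=M")
    for s in FEMALE_ONLY_SYMPTOMS:
        flag(male & (df[s] == 1), f"symptom {s} requires sex=F")
    return problem


def validate_cohort(df: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate a cohort frame; return it with canonical dtypes.

    In strict mode the first invariant violation aborts with its row number;
    in lenient mode violating rows are dropped and counted in the log.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort table is missing columns: {missing}")
    df = df.copy()
    for col in ("ever_smoker",) + SYMPTOMS:
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(-1).astype(int)
    problems = _row_problems(df)
    bad = problems != ""
    if bad.any():
        if strict:
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"row {df.index[i]}: {problems.iloc[i]} "
                f"(patient_id={df['patient_id'].iloc[i]!r})"
            )
        n_bad = int(bad.sum())
        log.warning("dropping %d invalid cohort rows (lenient mode)", n_bad)
        df = df.loc[~bad]
    df["age"] = df["age"].astype(float)
    df["time_months"] = df["time_months"].astype(float)
    df["patient_id"] = df["patient_id"].astype(str)
    extras = [c for c in df.columns if c not in COHORT_COLUMNS]
    return df[list(COHORT_COLUMNS) + extras]


def read_cohort(path: str | Path, strict: bool = True, sep: str = ",") -> pd.DataFrame:
    """Read and validate a delimiter-separated cohort table."""
    df = pd.read_csv(path, sep=sep)
    return validate_cohort(df, strict=strict)


def write_cohort(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep=sep, index=False)


def censor_for_fitting(df: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon`` months.

    Events after the horizon become (horizon, censored); applying a longer
    horizon first and then a shorter one equals applying the shorter directly.
    """
    if horizon <= 0:
        raise ValueError("censoring horizon must be positive")
    out = df.copy()
    late = out["time_months"] > horizon
    out.loc[late, "time_months"] = horizon
    out.loc[late, "outcome"] = CENSORED
    return out


def split_by_sex(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {sex: df[df["sex"] == sex].reset_index(drop=True) for sex in (FEMALE, MALE)}


# ---------------------------------------------------------------------------
# Design data for cause-specific model fitting


@dataclass
class DesignData:
    """Covariate arrays for one cause-specific fit.

    The symptom x log-time interactions are not expanded here; the model
    likelihood forms them from ``symptoms`` and ``log(time)`` itself.
    """

    time: NDArray
    event: NDArray          # 1 iff outcome == target (cause-specific censoring)
    age_basis: NDArray      # (n, m-1) from the age spline, or (n, 0)
    smoker: NDArray         # (n, 1) or (n, 0)
    symptoms: NDArray       # (n, S) in the spec's symptom order
    column_names: list[str]


def build_design_matrix(df: pd.DataFrame, spec) -> DesignData:
    """Encode a single-sex cohort for the given :class:`~symptomrisk.fpm.ModelSpec`.

    The event indicator is 1 only for the spec's target outcome; every other
    outcome (including competing events) is treated as censored at its time,
    the cause-specific convention.
    """
    from .spline_basis import rcs_basis  # local import keeps module deps one-way

    sexes = df["sex"].unique()
    if len(sexes) != 1 or sexes[0] != spec.sex:
        raise ValueError(
            f"design matrix for sex={spec.sex!r} given a cohort with sexes {sorted(sexes)}"
        )
    if spec.outcome not in outcomes_for_sex(spec.sex).event_codes:
        raise ValueError(f"outcome {spec.outcome!r} is not modelled for sex {spec.sex!r}")

    time = df["time_months"].to_numpy(float)
    event = (df["outcome"] == spec.outcome).to_numpy(float)
    names: list[str] = []
    if spec.include_age:
        if spec.age_spec is None:
            raise ValueError("spec.age_spec must be resolved before encoding")
        age_basis = rcs_basis(df["age"].to_numpy(float), spec.age_spec)
        names += [f"age_rcs{j + 1}" for j in range(age_basis.shape[1])]
    else:
        age_basis = np.zeros((len(df), 0))
    if spec.include_smoking:
        smoker = df["ever_smoker"].to_numpy(float)[:, None]
        names.append("ever_smoker")
    else:
        smoker = np.zeros((len(df), 0))
    symptoms = df[list(spec.symptoms)].to_numpy(float)
    names += list(spec.symptoms)
    return DesignData(
        time=time, event=event, age_basis=age_basis, smoker=smoker,
        symptoms=symptoms, column_names=names,
    )


def cancer_event_mask(df: pd.DataFrame, horizon: float | None = 12.0) -> pd.Series:
    """True where the first event is a cancer diagnosis (within ``horizon`` months)."""
    mask = df["outcome"].isin(CANCER_GROUPS)
    if horizon is not None:
        mask &= df["time_months"] <= horizon
    return mask


def death_event_mask(df: pd.DataFrame, horizon: float | None = 12.0) -> pd.Series:
    """True where the first event is death without a prior cancer diagnosis."""
    mask = df["outcome"] == "noncancer_death"
    if horizon is not None:
        mask &= df["time_months"] <= horizon
    return mask


# ---------------------------------------------------------------------------
# Model files (nested key-value text) so fit and predict can run separately


def save_model_file(payload: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_model_file(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
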