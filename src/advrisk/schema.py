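"""Cohort schema: column names, categorical levels, validation, CSV I/O.

One row per screening mammogram ("the screening exam is the unit of
analysis").  Covariates follow the BCSC risk-factor coding: five
race/ethnicity groups (all non-Hispanic except Hispanic), binary menopausal
status, binary first-degree family history, five-level benign-biopsy
history, four BI-RADS density categories, and five BMI categories.  The
outcome within the follow-up window (12 months after an annual screen,
24 months after a biennial screen) is one of three states: no event,
advanced breast cancer (invasive, prognostic pathologic stage II+), or a
competing event (death or early-stage cancer).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

ANNUAL = "annual"
BIENNIAL = "biennial"
INTERVALS = (ANNUAL, BIENNIAL)

RACE_LEVELS = ("Asian", "Black", "Hispanic", "White", "Other/Multiple")
MENOPAUSE_LEVELS = ("pre", "post")
FAMILY_HISTORY_LEVELS = ("no", "yes")
BIOPSY_LEVELS = (
    "none",
    "benign-unknown",
    "non-proliferative",
    "proliferative-no-atypia",
    "proliferative-atypia",
)
DENSITY_LEVELS = ("fatty", "scattered", "heterogeneous", "extreme")
BMI_LEVELS = ("underweight", "normal", "overweight", "obese-I", "obese-II/III")

OUTCOME_NONE = "none"
OUTCOME_ADVANCED = "advanced_cancer"
OUTCOME_COMPETING = "competing_event"
OUTCOME_LEVELS = (OUTCOME_NONE, OUTCOME_ADVANCED, OUTCOME_COMPETING)

AGE_MIN, AGE_MAX = 40.0, 74.0
AGE_GROUPS = ("40-49", "50-59", "60-69", "70-74")

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "race_ethnicity": RACE_LEVELS,
    "menopause": MENOPAUSE_LEVELS,
    "family_history": FAMILY_HISTORY_LEVELS,
    "biopsy_history": BIOPSY_LEVELS,
    "density": DENSITY_LEVELS,
    "bmi": BMI_LEVELS,
}

#: covariates that may carry item-level missingness (outcome and interval never do)
MASKABLE = (
    "menopause",
    "family_history",
    "biopsy_history",
    "density",
    "bmi",
    "race_ethnicity",
)

COLUMNS = (
    "woman_id",
    "round_index",
    "interval",
    "age",
    "race_ethnicity",
    "menopause",
    "family_history",
    "biopsy_history",
    "density",
    "bmi",
    "outcome",
)


class SchemaError(ValueError):
    """A cohort table violates the exam-level schema."""


def age_group(age: np.ndarray | pd.Series | float) -> np.ndarray:
    """Map age in years to the decade bands used for standardization."""
    age = np.asarray(age, dtype=float)
    bins = [-np.inf, 50.0, 60.0, 70.0, np.inf]
    idx = np.digitize(age, bins) - 1
    return np.asarray(AGE_GROUPS, dtype=object)[idx]


def validate_cohort(df: pd.DataFrame, allow_missing: bool = True) -> None:
    """Check column presence, level membership, age range, outcome domain.

    Raises :class:`SchemaError` naming the first offending column.
    """
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort is missing columns: {missing_cols}")
    if df["interval"].isna().any():
        raise SchemaError("interval must never be missing")
    if not df["interval"].isin(INTERVALS).all():
        raise SchemaError("interval has levels outside (annual, biennial)")
    if df["outcome"].isna().any():
        raise SchemaError("outcome must never be missing")
    if not df["outcome"].isin(OUTCOME_LEVELS).all():
        raise SchemaError("outcome has levels outside the three-state domain")
    age = df["age"].to_numpy(dtype=float)
    slack = 2.0 * (df["round_index"].to_numpy(dtype=float) - 1.0)
    if np.any(age < AGE_MIN) or np.any(age > AGE_MAX + slack):
        raise SchemaError("age outside the 40-74 screening range")
    for col, levels in CATEGORICAL_LEVELS.items():
        vals = df[col]
        ok = vals.isin(levels)
        if allow_missing:
            ok = ok | vals.isna()
        if not ok.all():
            bad = sorted(set(vals[~ok].dropna().astype(str)))
            raise SchemaError(f"column {col!r} has unexpected levels: {bad}")
        if not allow_missing and vals.isna().any():
            raise SchemaError(f"column {col!r} has missing values")


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; missing values become empty fields."""
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(
        path,
        dtype={c: object for c in CATEGORICAL_LEVELS},
        keep_default_na=True,
        na_values=[""],
    )
    validate_cohort(df)
    return df
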