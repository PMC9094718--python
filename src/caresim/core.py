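"""Shared vocabulary: state-vector schema, strata, and design matrices.

The simulated population lives in a :class:`pandas.DataFrame` with one row
per individual.  Columns follow the state vector of the microsimulation:
demographics (age, sex, education), eleven non-reversible chronic-condition
flags, functional status (ADL/IADL limitation counts), depression,
self-reported health, vital status, and the derived labels (dementia state,
frailty, long-term-care dependency tier).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

# --- strata -----------------------------------------------------------------

#: The eleven chronic conditions tracked by the transition engine.
CONDITIONS = (
    "diabetes",
    "chd",                # coronary heart disease
    "stroke",
    "hypertension",
    "hyperlipidaemia",
    "cancer",
    "respiratory",
    "joint",
    "eye",
    "kidney",             # chronic kidney disease / renal failure
    "other",
)

#: Subset entering the frailty risk model (seven comorbidities).
FRAILTY_CONDITIONS = (
    "diabetes",
    "chd",
    "stroke",
    "hypertension",
    "hyperlipidaemia",
    "cancer",
    "kidney",
)

EDUCATION_LEVELS = ("less_than_high_school", "high_school", "college_or_higher")
SEXES = ("male", "female")  # index: female column 0 = male, 1 = female

DEMENTIA_STATES = ("normal", "mci", "dementia")
DEPENDENCY_LEVELS = ("none", "mild", "high")

MAX_AGE = 105          # hard cap; the open 100+ band reuses its parameter cell
ADL_ITEMS = 6          # basic activities of daily living tracked
IADL_ITEMS = 7         # instrumental activities of daily living tracked

# --- five-year age bands 60-64 ... 95-99, 100+ ------------------------------

AGE_BAND_LOWER = tuple(range(60, 101, 5))  # 60, 65, ..., 100
AGE_BANDS = tuple(
    f"{lo}-{lo + 4}" if lo < 100 else "100+" for lo in AGE_BAND_LOWER
)
N_AGE_BANDS = len(AGE_BANDS)


def age_band_index(age) -> np.ndarray:
    """Index of the five-year band containing ``age`` (clipped to 60..100+)."""
    a = np.asarray(age, dtype=float)
    return np.clip((a - 60) // 5, 0, N_AGE_BANDS - 1).astype(np.intp)


def age_band_label(age) -> np.ndarray:
    return np.asarray(AGE_BANDS)[age_band_index(age)]


def age_band_midpoint(index) -> np.ndarray:
    """Representative age of a band (102 for the open 100+ band)."""
    lo = np.asarray(AGE_BAND_LOWER)[np.asarray(index, dtype=np.intp)]
    return np.where(lo >= 100, 102.0, lo + 2.0)


# --- covariate sets ----------------------------------------------------------

#: Covariates of the multivariate probit of cognitive-test failure / IADL
#: difficulty: age, sex, educational attainment and multi-comorbidity.
PROBIT_COVARIATES = ("const", "age_c", "female", "edu_hs", "edu_college", "n_conditions")

#: Covariates of the logistic frailty model: age, sex, education, seven
#: comorbid conditions, depression, and impaired mobility in daily living.
FRAILTY_COVARIATES = (
    ("const", "age_c", "female", "edu_hs", "edu_college")
    + FRAILTY_CONDITIONS
    + ("depression", "impaired_mobility")
)

#: Covariates of the monthly health-care use regressions: age, sex and the
#: eleven comorbidity flags.  The comorbidity count is exactly the sum of
#: the flags, so it cannot enter the same linear design (estimation software
#: would silently omit it); it is reported descriptively in the per-capita
#: cost tables instead.
COST_COVARIATES = ("const", "age_c", "female") + CONDITIONS

AGE_CENTER = 75.0
AGE_SCALE = 10.0


def age_centered(age) -> np.ndarray:
    """Standardised age covariate ``(age - 75) / 10`` used by all regressions."""
    return (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE


def design_matrix(df: pd.DataFrame, covariates) -> np.ndarray:
    """Build the (n, k) design matrix for ``covariates`` from a person table.

    Derived columns (``const``, ``age_c``, education dummies,
    ``n_conditions``, ``impaired_mobility``) are computed on the fly; any
    other name must be a column of ``df``.
    """
    n = len(df)
    cols = []
    for name in covariates:
        if name == "const":
            cols.append(np.ones(n))
        elif name == "age_c":
            cols.append(age_centered(df["age"].to_numpy()))
        elif name == "edu_hs":
            cols.append((df["education"].to_numpy() == 1).astype(float))
        elif name == "edu_college":
            cols.append((df["education"].to_numpy() == 2).astype(float))
        elif name == "n_conditions":
            cols.append(
                sum(df[c].to_numpy(dtype=float) for c in CONDITIONS)
            )
        elif name == "impaired_mobility" and name not in df.columns:
            cols.append(impaired_mobility(df).astype(float))
        elif name in df.columns:
            cols.append(df[name].to_numpy(dtype=float))
        else:
            raise DataError(f"covariate {name!r} not found in table")
    return np.column_stack(cols)


def impaired_mobility(df: pd.DataFrame) -> np.ndarray:
    """Impaired mobility in daily living, mapped from functional status.

    Defined as any basic-ADL limitation or at least two IADL difficulties;
    the mapping is a modelling choice (see docs/methods.md) and can be
    overridden by providing an ``impaired_mobility`` column directly.
    """
    return (
        (df["adl_limited"].to_numpy() >= 1) | (df["iadl_limited"].to_numpy() >= 2)
    )


# --- population schema -------------------------------------------------------

POPULATION_COLUMNS = (
    ("id", np.int64),
    ("age", np.float64),
    ("female", np.int8),
    ("education", np.int8),
    *((c, np.int8) for c in CONDITIONS),
    ("adl_limited", np.int8),
    ("iadl_limited", np.int8),
    ("depression", np.int8),
    ("self_reported_health", np.int8),
    ("alive", np.bool_),
    ("dementia_state", np.int8),
    ("frail", np.int8),
    ("dependency", np.int8),
)


def empty_population(n: int) -> pd.DataFrame:
    """Allocate a population frame with ``n`` rows and schema defaults."""
    data = {}
    for name, dtype in POPULATION_COLUMNS:
        data[name] = np.zeros(n, dtype=dtype)
    df = pd.DataFrame(data)
    df["alive"] = True
    df["self_reported_health"] = np.int8(3)
    return df


def validate_population(df: pd.DataFrame) -> None:
    missing = [name for name, _ in POPULATION_COLUMNS if name not in df.columns]
    if missing:
        raise DataError(f"population table missing columns: {missing}")
    if df["id"].duplicated().any():
        raise DataError("population ids are not unique")
    if (df["iadl_limited"] > IADL_ITEMS).any():
        raise DataError(f"iadl_limited exceeds {IADL_ITEMS}")
    if (df["adl_limited"] > ADL_ITEMS).any():
        raise DataError(f"adl_limited exceeds {ADL_ITEMS}")


def condition_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 11) float matrix of the chronic-condition flags."""
    return np.column_stack([df[c].to_numpy(dtype=float) for c in CONDITIONS])
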