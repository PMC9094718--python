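"""Health-care and long-term-care cost model.

Three layers:

* **Health care** — per-person expected monthly use by service type
  (inpatient vs outpatient + prescription) from least-squares regressions on
  age, sex, the eleven comorbidities and the comorbidity count; annualised
  as 12x the predicted monthly use, floored at zero.
* **Formal long-term care** — the seven public long-term-care-insurance
  eligibility levels collapsed into two dependency tiers (mild: the lower
  three levels; high: the upper four, requiring support in basic activities
  of daily life); mean monthly cost looked up by age band x sex x tier x
  service setting (home/community-based vs care homes) and annualised.
  Care-home residence is assigned stochastically from an age-tier residence
  probability table.
* **Informal care** — unpaid (mostly family) caregiving hours for
  home-based dependent persons: 25 h/week for high dependency, 10 h/week
  for mild, valued at $11/hour: 25x52x11 = $14,300 and 10x52x11 = $5,720
  per year.  Care-home residents and persons with no dependency receive no
  informal care.

All monetary values are annual, in constant 2016 US dollars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    AGE_BANDS,
    COST_COVARIATES,
    N_AGE_BANDS,
    SEXES,
    age_band_index,
    design_matrix,
)
from .errors import ConfigurationError, DataError, MissingStratumError
from .synthetic import SERVICE_TYPES

__all__ = [
    "CostParameters",
    "default_ltc_monthly_use",
    "default_residence_probability",
    "fit_healthcare_use",
    "assign_dependency_level",
    "annual_costs",
    "annual_cost_individual",
    "aggregate_costs",
    "substitution_sensitivity",
    "COST_COMPONENTS",
    "CONDITION_GROUPS",
]

DEPENDENCY_TIERS = ("none", "mild", "high")
LTC_SETTINGS = ("home_community", "care_home")
COST_COMPONENTS = ("inpatient", "outpatient_rx", "ltc_home_community", "ltc_care_home", "informal")
CONDITION_GROUPS = ("neither", "dementia_only", "frailty_only", "both")

WEEKS_PER_YEAR = 52


def default_ltc_monthly_use() -> pd.DataFrame:
    """Mean monthly formal-care cost (US$) by age band x sex x tier x setting.

    Synthetic stand-in for the claims-based table: costs rise mildly with
    age band, high dependency costs more than mild, and care-home stays
    cost more than home/community care.
    """
    base = {
        ("mild", "home_community"): 600.0,
        ("mild", "care_home"): 2400.0,
        ("high", "home_community"): 1500.0,
        ("high", "care_home"): 3200.0,
    }
    rows = []
    for b in range(N_AGE_BANDS):
        for sex in SEXES:
            for (tier, setting), cost in base.items():
                rows.append(
                    (AGE_BANDS[b], sex, tier, setting, cost * (1.0 + 0.02 * b))
                )
    return pd.DataFrame(
        rows, columns=["age_band", "sex", "dependency", "setting", "monthly_cost"]
    )


def default_residence_probability() -> pd.DataFrame:
    """P(care-home residence | dependency tier, age band)."""
    rows = []
    for b in range(N_AGE_BANDS):
        rows.append((AGE_BANDS[b], "mild", min(0.02 + 0.012 * b, 0.15)))
        rows.append((AGE_BANDS[b], "high", min(0.10 + 0.035 * b, 0.45)))
    return pd.DataFrame(rows, columns=["age_band", "dependency", "p_care_home"])


@dataclass
class CostParameters:
    """Coefficients and tables of the cost model.

    Attributes
    ----------
    healthcare_coefficients : DataFrame
        Service type x :data:`caresim.core.COST_COVARIATES` monthly-use
        regression coefficients.
    ltc_monthly_use : DataFrame
        Columns ``age_band, sex, dependency, setting, monthly_cost``.
    residence_probability : DataFrame
        Columns ``age_band, dependency, p_care_home``.
    informal_hours : dict
        Weekly informal-care hours by tier (default high 25, mild 10).
    informal_wage : float
        Hourly valuation of informal care (default $11, 2016).
    """

    healthcare_coefficients: pd.DataFrame
    ltc_monthly_use: pd.DataFrame = field(default_factory=default_ltc_monthly_use)
    residence_probability: pd.DataFrame = field(default_factory=default_residence_probability)
    informal_hours: dict = field(default_factory=lambda: {"high": 25.0, "mild": 10.0})
    informal_wage: float = 11.0
    currency_year: int = 2016

    def __post_init__(self):
        if list(self.healthcare_coefficients.columns) != list(COST_COVARIATES):
            raise ConfigurationError(
                f"healthcare coefficient columns must be {COST_COVARIATES}"
            )
        if (self.ltc_monthly_use["monthly_cost"] < 0).any():
            raise ConfigurationError("monthly formal-care costs must be >= 0")
        if self.informal_wage <= 0 or min(self.informal_hours.values()) <= 0:
            raise ConfigurationError("informal-care constants must be positive")

    def informal_annual(self, tier: str) -> float:
        """Annual informal-care cost for a home-based person of ``tier``."""
        if tier == "none":
            return 0.0
        return float(self.informal_hours[tier] * WEEKS_PER_YEAR * self.informal_wage)

    def _ltc_array(self) -> np.ndarray:
        """(bands, 2, 2 tiers, 2 settings) monthly-cost lookup array."""
        arr = np.full((N_AGE_BANDS, 2, 2, 2), np.nan)
        band_i = {b: i for i, b in enumerate(AGE_BANDS)}
        sex_i = {s: i for i, s in enumerate(SEXES)}
        tier_i = {"mild": 0, "high": 1}
        set_i = {s: i for i, s in enumerate(LTC_SETTINGS)}
        for row in self.ltc_monthly_use.itertuples(index=False):
            arr[
                band_i[row.age_band], sex_i[row.sex], tier_i[row.dependency], set_i[row.setting]
            ] = row.monthly_cost
        if np.isnan(arr).any():
            idx = np.argwhere(np.isnan(arr))[0]
            raise MissingStratumError(
                "ltc_monthly_use",
                age_band=AGE_BANDS[idx[0]],
                sex=SEXES[idx[1]],
                dependency=("mild", "high")[idx[2]],
                setting=LTC_SETTINGS[idx[3]],
            )
        return arr

    def _residence_array(self) -> np.ndarray:
        """(bands, 2 tiers) care-home probability lookup array."""
        arr = np.full((N_AGE_BANDS, 2), np.nan)
        band_i = {b: i for i, b in enumerate(AGE_BANDS)}
        tier_i = {"mild": 0, "high": 1}
        for row in self.residence_probability.itertuples(index=False):
            arr[band_i[row.age_band], tier_i[row.dependency]] = row.p_care_home
        if np.isnan(arr).any():
            idx = np.argwhere(np.isnan(arr))[0]
            raise MissingStratumError(
                "residence_probability",
                age_band=AGE_BANDS[idx[0]],
                dependency=("mild", "high")[idx[1]],
            )
        return arr


def fit_healthcare_use(
    claims: pd.DataFrame, covariates=COST_COVARIATES, services=SERVICE_TYPES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Least-squares monthly-use regressions per service type.

    Returns ``(coefficients, standard_errors)`` DataFrames indexed by
    service type.  Rank-deficient designs raise an error naming the
    collinear columns.
    """
    X = design_matrix(claims, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [covariates[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise DataError(f"design matrix is rank deficient; collinear columns: {bad}")
    coefs, ses = {}, {}
    for svc in services:
        if svc not in claims.columns:
            raise DataError(f"claims table has no column for service type {svc!r}")
        res = sm.OLS(claims[svc].to_numpy(dtype=float), X).fit()
        coefs[svc] = res.params
        ses[svc] = res.bse
    coef = pd.DataFrame(coefs, index=list(covariates)).T
    se = pd.DataFrame(ses, index=list(covariates)).T
    return coef, se


def assign_dependency_level(persons: pd.DataFrame) -> np.ndarray:
    """Dependency tier (0 none, 1 mild, 2 high) from functional state.

    High dependency — any basic-ADL limitation (support needed in bathing,
    toileting, eating); mild — IADL limitation or frailty without ADL
    limitation; none otherwise.  This is the seven-level public LTCI scale
    collapsed to the two costing tiers.
    """
    single = isinstance(persons, pd.Series)
    if single:
        persons = persons.to_frame().T
    adl = persons["adl_limited"].to_numpy(dtype=int)
    iadl = persons["iadl_limited"].to_numpy(dtype=int)
    frail = persons["frail"].to_numpy(dtype=int) if "frail" in persons.columns else 0
    out = np.where(adl >= 1, 2, np.where((iadl >= 1) | (frail == 1), 1, 0)).astype(np.int8)
    return out[0] if single else out


def _condition_group(persons: pd.DataFrame) -> np.ndarray:
    dem = persons["dementia_state"].to_numpy(dtype=int) == 2
    fra = persons["frail"].to_numpy(dtype=int) == 1
    out = np.full(len(persons), "neither", dtype=object)
    out[dem & ~fra] = "dementia_only"
    out[~dem & fra] = "frailty_only"
    out[dem & fra] = "both"
    return out


def annual_costs(
    persons: pd.DataFrame,
    params: CostParameters,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-person annual cost breakdown for the (live) persons given.

    Returns a frame aligned with ``persons`` carrying the five cost
    components, the dependency tier, the care-home flag and the condition
    group.  Components are all non-negative and ``total`` is their exact
    sum.
    """
    n = len(persons)
    X = design_matrix(persons, COST_COVARIATES)
    out = pd.DataFrame(index=persons.index)
    for svc in SERVICE_TYPES:
        monthly = X @ params.healthcare_coefficients.loc[svc].to_numpy()
        out[svc] = 12.0 * np.maximum(monthly, 0.0)

    dependency = assign_dependency_level(persons)
    band = age_band_index(persons["age"].to_numpy())
    sexi = persons["female"].to_numpy(dtype=np.intp)

    res_arr = params._residence_array()
    p_home = np.zeros(n)
    tiered = dependency > 0
    p_home[tiered] = res_arr[band[tiered], dependency[tiered] - 1]
    care_home = tiered & (rng.random(n) < p_home)

    ltc_arr = params._ltc_array()
    ltc_home = np.zeros(n)
    ltc_inst = np.zeros(n)
    home_based = tiered & ~care_home
    ltc_home[home_based] = 12.0 * ltc_arr[
        band[home_based], sexi[home_based], dependency[home_based] - 1, 0
    ]
    ltc_inst[care_home] = 12.0 * ltc_arr[
        band[care_home], sexi[care_home], dependency[care_home] - 1, 1
    ]
    out["ltc_home_community"] = ltc_home
    out["ltc_care_home"] = ltc_inst

    informal = np.zeros(n)
    for t, tier in ((1, "mild"), (2, "high")):
        mask = home_based & (dependency == t)
        informal[mask] = params.informal_annual(tier)
    out["informal"] = informal

    out["total"] = out[list(COST_COMPONENTS)].sum(axis=1)
    out["dependency"] = dependency
    out["care_home"] = care_home
    out["group"] = _condition_group(persons)
    out["female"] = persons["female"].to_numpy()
    out["education"] = persons["education"].to_numpy()
    return out


def annual_cost_individual(
    person: pd.Series, params: CostParameters, care_home: bool | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Cost breakdown for one person.

    Residence is taken from ``care_home`` when given, otherwise drawn from
    the residence probability table with ``rng``.
    """
    frame = person.to_frame().T
    if care_home is not None:
        params = CostParameters(
            healthcare_coefficients=params.healthcare_coefficients,
            ltc_monthly_use=params.ltc_monthly_use,
            residence_probability=params.residence_probability.assign(
                p_care_home=1.0 if care_home else 0.0
            ),
            informal_hours=params.informal_hours,
            informal_wage=params.informal_wage,
            currency_year=params.currency_year,
        )
        rng = np.random.default_rng(0)
    elif rng is None:
        raise ConfigurationError("provide either care_home or rng")
    return annual_costs(frame, params, rng).iloc[0]


def aggregate_costs(costed: pd.DataFrame, persons: pd.DataFrame | None = None,
                    weight: float = 1.0) -> dict:
    """Aggregate per-person breakdowns to totals and per-capita strata.

    Returns a dict of DataFrames:

    ``totals``
        Annual totals by component x condition group (the four disjoint
        groups), plus overlapping ``dementia`` / ``frailty`` attributions
        (each includes the ``both`` group, matching headline-style
        reporting) and the grand total.
    ``per_capita``
        Mean annual cost by sex x education x {total population, without
        dementia or frailty, with dementia or frailty or both} for the
        aggregated components (healthcare, formal LTC, informal), plus the
        mean comorbidity count when ``persons`` is given.
    """
    comp = list(COST_COMPONENTS)
    totals_by_group = costed.groupby("group")[comp].sum().reindex(
        list(CONDITION_GROUPS), fill_value=0.0
    )
    rows = []
    for grp in CONDITION_GROUPS:
        for c in comp:
            rows.append((grp, c, weight * totals_by_group.loc[grp, c]))
    overlap = {
        "dementia": ["dementia_only", "both"],
        "frailty": ["frailty_only", "both"],
        "any": ["dementia_only", "frailty_only", "both"],
        "all": list(CONDITION_GROUPS),
    }
    for label, groups in overlap.items():
        for c in comp:
            rows.append((label, c, weight * totals_by_group.loc[groups, c].sum()))
    totals = pd.DataFrame(rows, columns=["group", "component", "total"])

    healthcare = costed["inpatient"] + costed["outpatient_rx"]
    ltc = costed["ltc_home_community"] + costed["ltc_care_home"]
    work = pd.DataFrame(
        {
            "female": costed["female"],
            "education": costed["education"],
            "healthcare": healthcare,
            "formal_ltc": ltc,
            "informal": costed["informal"],
            "affected": (costed["group"] != "neither"),
        }
    )
    if persons is not None:
        from .core import CONDITIONS

        work["n_comorbidities"] = sum(
            persons[c].to_numpy(dtype=float) for c in CONDITIONS
        )
    pc_rows = []
    value_cols = [c for c in ("healthcare", "formal_ltc", "informal", "n_comorbidities")
                  if c in work.columns]
    for (female, edu), part in work.groupby(["female", "education"]):
        subsets = {
            "total": part,
            "without_dementia_or_frailty": part[~part["affected"]],
            "with_dementia_or_frailty": part[part["affected"]],
        }
        for label, sub in subsets.items():
            rec = {
                "female": female,
                "education": edu,
                "population": label,
                "n": len(sub),
            }
            for c in value_cols:
                rec[c] = float(sub[c].mean()) if len(sub) else np.nan
            pc_rows.append(rec)
    per_capita = pd.DataFrame(pc_rows)
    return {"totals": totals, "per_capita": per_capita}


def substitution_sensitivity(
    totals: pd.DataFrame,
    household_capacity_decline: float = 0.20,
    substitution_rate: float = 0.13,
) -> pd.DataFrame:
    """Household-capacity sensitivity scenario on a totals table.

    Informal-care volume falls by the household-capacity decline (default
    20%) and formal community-based home care rises by the substitution
    rate (default 13%).  Returns the adjusted table with a
    ``formal_plus_informal`` summary row appended per group.
    """
    for name, r in (
        ("household_capacity_decline", household_capacity_decline),
        ("substitution_rate", substitution_rate),
    ):
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {r}")
    adj = totals.copy()
    informal = adj["component"] == "informal"
    home = adj["component"] == "ltc_home_community"
    adj.loc[informal, "total"] *= 1.0 - household_capacity_decline
    adj.loc[home, "total"] *= 1.0 + substitution_rate
    combined = (
        adj.groupby("group", as_index=False)["total"]
        .sum()
        .assign(component="formal_plus_informal")
    )
    return pd.concat([adj, combined[["group", "component", "total"]]], ignore_index=True)
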