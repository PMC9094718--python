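"""Synthetic input generation with known ground truth.

The original study drew on restricted Japanese microdata (nationally
representative health surveys, a cognitive-test survey, a community frailty
survey, health-insurance and long-term-care claims).  None of those sources
are redistributable, so this module generates statistically analogous
person-level fixtures with *known* coefficients: baseline populations with
age/sex/education gradients in chronic conditions, a cognitive survey with
correlated binary test-failure and IADL-difficulty outcomes from a latent
multivariate normal (probit structure), a frailty survey with a logistic
phenotype, monthly utilization claims linked to comorbidity burden, and the
calibration target prevalence curves.  All distributional shapes (logistic
age gradients, Gompertz-style mortality) are generator choices documented in
the defaults; parameter-recovery tests confirm each fixture supports
refitting its own truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import derive_rng
from .core import (
    ADL_ITEMS,
    AGE_BANDS,
    AGE_BAND_LOWER,
    CONDITIONS,
    FRAILTY_COVARIATES,
    IADL_ITEMS,
    N_AGE_BANDS,
    PROBIT_COVARIATES,
    COST_COVARIATES,
    SEXES,
    age_band_index,
    age_band_midpoint,
    design_matrix,
    empty_population,
)
from .engine import TransitionParameters
from .errors import ConfigurationError, DataError

__all__ = [
    "GeneratorConfig",
    "TruthParameters",
    "CalibrationTarget",
    "default_config",
    "default_truth",
    "generate_baseline_population",
    "generate_transition_parameters",
    "generate_cognitive_survey",
    "generate_frailty_survey",
    "generate_utilization_claims",
    "generate_target_prevalence",
    "DEFAULT_TARGET_CURVES",
]

#: Outcome labels of the cognitive battery (3 tests) and IADL items (7).
COGNITIVE_TESTS = ("recall_immediate", "recall_delayed", "serial_sevens")
IADL_OUTCOMES = (
    "iadl_transport",
    "iadl_shopping",
    "iadl_meals",
    "iadl_bills",
    "iadl_banking",
    "iadl_telephone",
    "iadl_medication",
)
PROBIT_OUTCOMES = COGNITIVE_TESTS + IADL_OUTCOMES

SERVICE_TYPES = ("inpatient", "outpatient_rx")


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

# per-condition baseline logits: (intercept at age 75, slope per year of age,
# female, high-school, college-or-higher) on the log-odds scale
_DEFAULT_CONDITION_LOGITS = {
    "diabetes": (-1.7, 0.030, -0.35, -0.10, -0.25),
    "chd": (-2.3, 0.050, -0.40, -0.05, -0.15),
    "stroke": (-2.8, 0.060, -0.30, -0.10, -0.30),
    "hypertension": (-0.3, 0.045, 0.05, -0.05, -0.15),
    "hyperlipidaemia": (-1.4, 0.000, 0.35, 0.00, 0.05),
    "cancer": (-2.5, 0.045, -0.25, 0.00, 0.05),
    "respiratory": (-2.6, 0.040, -0.25, -0.10, -0.20),
    "joint": (-1.6, 0.035, 0.45, -0.10, -0.20),
    "eye": (-1.8, 0.050, 0.15, -0.05, -0.10),
    "kidney": (-3.0, 0.050, -0.30, -0.05, -0.15),
    "other": (-1.2, 0.010, 0.00, 0.00, 0.00),
}

_DEFAULT_EDUCATION_SHARES = {
    # cohorts aged 60+ as of the mid-2010s: women had less access to
    # tertiary education than men
    "female": (0.45, 0.45, 0.10),
    "male": (0.35, 0.45, 0.20),
}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic baseline population and parameters.

    Attributes
    ----------
    population_size : int
        Number of simulated persons at baseline.
    start_year : int
        Calendar year of the baseline (default 2016).
    age_range : tuple of int
        Inclusive baseline age range; the minimum must be >= 60.
    education_shares : dict
        Per-sex shares (less-than-high-school, high-school,
        college-or-higher); each triple sums to 1.
    female_share : float
        Share of women at baseline (women outnumber men at older ages).
    age_slope : float
        Exponential decline rate of the baseline age pyramid per year of age.
    condition_baseline_logits : dict
        Per-condition (intercept at 75, age slope /yr, female, edu_hs,
        edu_college) on the log-odds scale.
    seed : int
        Master RNG seed for the run; module sub-streams are derived from it.
    """

    population_size: int
    start_year: int = 2016
    age_range: tuple = (60, 99)
    education_shares: dict = field(
        default_factory=lambda: dict(_DEFAULT_EDUCATION_SHARES)
    )
    female_share: float = 0.55
    age_slope: float = 0.045
    condition_baseline_logits: dict = field(
        default_factory=lambda: dict(_DEFAULT_CONDITION_LOGITS)
    )
    # functional-status baselines: (logit intercept at 60, slope per year)
    adl_item_logit: tuple = (-4.5, 0.07)
    iadl_item_logit: tuple = (-4.0, 0.075)
    depression_logit: tuple = (-2.6, 0.010)
    # Gompertz mortality: log annual hazard = a_sex + b * age
    mortality_gompertz: dict = field(
        default_factory=lambda: {"female": (-14.41, 0.13), "male": (-12.93, 0.12)}
    )
    mortality_education_hr: tuple = (1.15, 1.0, 0.85)
    incidence_education_hr: tuple = (1.10, 1.0, 0.85)
    # per-condition annual incidence: (log hazard at 70, slope per year)
    incidence_gompertz: dict = field(
        default_factory=lambda: {
            "diabetes": (np.log(0.008), 0.010),
            "chd": (np.log(0.006), 0.040),
            "stroke": (np.log(0.005), 0.055),
            "hypertension": (np.log(0.030), 0.020),
            "hyperlipidaemia": (np.log(0.012), 0.000),
            "cancer": (np.log(0.008), 0.040),
            "respiratory": (np.log(0.005), 0.045),
            "joint": (np.log(0.012), 0.025),
            "eye": (np.log(0.012), 0.050),
            "kidney": (np.log(0.003), 0.055),
            "other": (np.log(0.020), 0.010),
        }
    )
    condition_mortality_loghr: dict = field(
        default_factory=lambda: {
            "diabetes": 0.25,
            "chd": 0.35,
            "stroke": 0.45,
            "hypertension": 0.05,
            "hyperlipidaemia": 0.00,
            "cancer": 0.55,
            "respiratory": 0.30,
            "joint": 0.05,
            "eye": 0.00,
            "kidney": 0.40,
            "other": 0.10,
        }
    )
    # functional decline per half-year: (logit intercept at 60, slope per yr)
    adl_decline_logit: tuple = (-6.0, 0.075)
    iadl_decline_logit: tuple = (-5.4, 0.080)
    depression_onset_logit: tuple = (-5.8, 0.020)
    srh_worsen_prob: float = 0.02
    # annual entry cohort (ages 60-62), as a fraction of the baseline size;
    # education composition improves over calendar time
    # annual cohort turning 60 as a share of the 60+ baseline population
    # (Japan mid-2010s: roughly 1.5M new 60-year-olds vs 44M aged 60+)
    entry_rate: float = 0.035
    entry_college_share: tuple = (0.22, 0.008, 0.45)  # (at start, +/yr, cap)
    entry_lths_share: tuple = (0.28, -0.008, 0.05)    # (at start, +/yr, floor)
    pre_entry_survival: float = 0.97
    seed: int = 0

    def __post_init__(self):
        if self.population_size <= 0:
            raise ConfigurationError("population_size must be positive")
        lo, hi = self.age_range
        if not (60 <= lo <= hi):
            raise ConfigurationError(
                "age_range must be ordered with minimum >= 60 at baseline"
            )
        for sex in SEXES:
            shares = np.asarray(self.education_shares[sex], dtype=float)
            if shares.shape != (3,) or (shares < 0).any():
                raise ConfigurationError(f"education_shares[{sex!r}] must be 3 non-negatives")
            if abs(shares.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"education_shares[{sex!r}] must sum to 1 (got {shares.sum()!r})"
                )
        if not 0.0 <= self.female_share <= 1.0:
            raise ConfigurationError("female_share must be in [0, 1]")


def default_config(population_size: int = 20_000, seed: int = 0, **overrides) -> GeneratorConfig:
    """The study conditions: 2016 baseline, ages 60+, 27-year projections."""
    return GeneratorConfig(population_size=population_size, seed=seed, **overrides)


@dataclass
class TruthParameters:
    """Ground-truth coefficients behind the survey and claims fixtures.

    These play the role of the estimated models (multivariate probit of
    cognitive-test failure / IADL difficulty, logistic frailty model,
    monthly-use regressions); generators draw from them and fitting should
    recover them.
    """

    probit_coefficients: pd.DataFrame  # outcomes x PROBIT_COVARIATES
    probit_correlation: np.ndarray     # (10, 10), unit diagonal, PD
    frailty_logit_coefficients: pd.Series  # over FRAILTY_COVARIATES
    cost_coefficients: pd.DataFrame    # services x COST_COVARIATES
    cost_noise_sd: dict = field(
        default_factory=lambda: {"inpatient": 120.0, "outpatient_rx": 120.0}
    )

    def __post_init__(self):
        self.probit_correlation = np.asarray(self.probit_correlation, dtype=float)
        R = self.probit_correlation
        if R.shape != (len(PROBIT_OUTCOMES),) * 2:
            raise ConfigurationError("probit_correlation has wrong shape")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError("probit_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ConfigurationError("probit_correlation must be positive definite")
        if list(self.probit_coefficients.columns) != list(PROBIT_COVARIATES):
            raise ConfigurationError(
                f"probit_coefficients columns must be {PROBIT_COVARIATES}"
            )
        if list(self.frailty_logit_coefficients.index) != list(FRAILTY_COVARIATES):
            raise ConfigurationError(
                f"frailty_logit_coefficients index must be {FRAILTY_COVARIATES}"
            )
        if list(self.cost_coefficients.columns) != list(COST_COVARIATES):
            raise ConfigurationError(f"cost_coefficients columns must be {COST_COVARIATES}")


def default_truth(probit_rho: float = 0.3) -> TruthParameters:
    """Default truth: exchangeable latent correlation, age-graded impairment.

    Coefficients are on the scale of the standardised covariates
    (``age_c = (age - 75) / 10``) and chosen so marginal outcome rates at
    typical survey ages fall in the 5-30% range.
    """
    rows = {}
    for t in COGNITIVE_TESTS:
        rows[t] = [-1.00, 0.90, -0.05, -0.30, -0.60, 0.12]
    for l in IADL_OUTCOMES:
        rows[l] = [-1.80, 1.00, 0.00, -0.20, -0.40, 0.15]
    probit = pd.DataFrame.from_dict(rows, orient="index", columns=list(PROBIT_COVARIATES))
    probit = probit.loc[list(PROBIT_OUTCOMES)]

    k = len(PROBIT_OUTCOMES)
    R = np.full((k, k), probit_rho)
    np.fill_diagonal(R, 1.0)

    frail = pd.Series(0.0, index=list(FRAILTY_COVARIATES))
    frail["const"] = -3.0
    frail["age_c"] = 1.10
    frail["female"] = 0.25
    frail["edu_hs"] = -0.20
    frail["edu_college"] = -0.40
    frail["diabetes"] = 0.30
    frail["chd"] = 0.25
    frail["stroke"] = 0.40
    frail["hypertension"] = 0.10
    frail["hyperlipidaemia"] = 0.05
    frail["cancer"] = 0.20
    frail["kidney"] = 0.35
    frail["depression"] = 0.50
    frail["impaired_mobility"] = 1.20

    cost = pd.DataFrame(0.0, index=list(SERVICE_TYPES), columns=list(COST_COVARIATES))
    cost.loc["inpatient"] = [
        350.0, 60.0, -20.0,
        40.0, 90.0, 120.0, 20.0, 10.0, 150.0, 60.0, 25.0, 15.0, 80.0, 30.0,
    ]
    cost.loc["outpatient_rx"] = [
        420.0, 30.0, 10.0,
        55.0, 45.0, 40.0, 35.0, 30.0, 60.0, 40.0, 30.0, 25.0, 50.0, 20.0,
    ]
    return TruthParameters(
        probit_coefficients=probit,
        probit_correlation=R,
        frailty_logit_coefficients=frail,
        cost_coefficients=cost,
    )


# ---------------------------------------------------------------------------
# baseline population
# ---------------------------------------------------------------------------

def _draw_demographics(n, config: GeneratorConfig, rng) -> pd.DataFrame:
    lo, hi = config.age_range
    ages = np.arange(lo, hi + 1)
    w = np.exp(-config.age_slope * (ages - lo))
    w /= w.sum()
    df = empty_population(n)
    df["id"] = np.arange(n, dtype=np.int64)
    df["age"] = rng.choice(ages, size=n, p=w).astype(float)
    df["female"] = (rng.random(n) < config.female_share).astype(np.int8)
    edu = np.zeros(n, dtype=np.int8)
    for s, sex in enumerate(SEXES):
        mask = df["female"].to_numpy() == s
        shares = np.asarray(config.education_shares[sex], dtype=float)
        edu[mask] = rng.choice(3, size=int(mask.sum()), p=shares).astype(np.int8)
    df["education"] = edu
    return df


def condition_probability(config: GeneratorConfig, condition: str, age, female, education):
    """Closed-form logistic baseline prevalence used by the generator."""
    b0, b_age, b_f, b_hs, b_col = config.condition_baseline_logits[condition]
    eta = (
        b0
        + b_age * (np.asarray(age, dtype=float) - 75.0)
        + b_f * np.asarray(female, dtype=float)
        + b_hs * (np.asarray(education) == 1)
        + b_col * (np.asarray(education) == 2)
    )
    return expit(eta)


def generate_baseline_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the baseline population table (all persons alive).

    Chronic-condition flags follow per-condition logistic models with
    age/sex/education gradients; ADL/IADL limitation counts are binomial
    with logistic item probabilities rising in age; depression and
    self-reported health likewise.
    """
    rng = derive_rng(config.seed, "baseline")
    df = _draw_demographics(config.population_size, config, rng)
    age = df["age"].to_numpy()
    female = df["female"].to_numpy()
    edu = df["education"].to_numpy()
    n = len(df)

    for cond in CONDITIONS:
        p = condition_probability(config, cond, age, female, edu)
        df[cond] = (rng.random(n) < p).astype(np.int8)

    a0, a1 = config.adl_item_logit
    df["adl_limited"] = rng.binomial(ADL_ITEMS, expit(a0 + a1 * (age - 60))).astype(np.int8)
    i0, i1 = config.iadl_item_logit
    df["iadl_limited"] = rng.binomial(IADL_ITEMS, expit(i0 + i1 * (age - 60))).astype(np.int8)
    d0, d1 = config.depression_logit
    df["depression"] = (rng.random(n) < expit(d0 + d1 * (age - 60))).astype(np.int8)
    srh = np.clip(np.rint(rng.normal(2.6 + 0.012 * (age - 60), 0.9)), 1, 5)
    df["self_reported_health"] = srh.astype(np.int8)
    df["alive"] = True
    return df


# ---------------------------------------------------------------------------
# transition parameters
# ---------------------------------------------------------------------------

def generate_transition_parameters(
    config: GeneratorConfig, horizon_years: int = 30
) -> TransitionParameters:
    """Half-year incidence and mortality tables plus the entry schedule.

    Mortality follows a Gompertz law ``q = 1 - exp(-0.5 * exp(a + b*age) * hr_edu)``
    evaluated at band midpoints, with lower hazards at higher educational
    attainment; condition incidence follows per-condition Gompertz-style
    hazards.  Both are therefore monotone non-decreasing in age.
    """
    mid = age_band_midpoint(np.arange(N_AGE_BANDS))
    incidence = np.zeros((N_AGE_BANDS, 2, 3, len(CONDITIONS)))
    mortality = np.zeros((N_AGE_BANDS, 2, 3))
    for s, sex in enumerate(SEXES):
        a, b = config.mortality_gompertz[sex]
        for e in range(3):
            hr = config.mortality_education_hr[e]
            mortality[:, s, e] = -np.expm1(-0.5 * np.exp(a + b * mid) * hr)
            ihr = config.incidence_education_hr[e]
            for j, cond in enumerate(CONDITIONS):
                ia, ib = config.incidence_gompertz[cond]
                haz = np.exp(ia + ib * (mid - 70.0)) * ihr
                incidence[:, s, e, j] = -np.expm1(-0.5 * haz)
    functional = {
        "adl": expit(config.adl_decline_logit[0] + config.adl_decline_logit[1] * (mid - 60)),
        "iadl": expit(config.iadl_decline_logit[0] + config.iadl_decline_logit[1] * (mid - 60)),
        "depression": expit(
            config.depression_onset_logit[0] + config.depression_onset_logit[1] * (mid - 60)
        ),
        "srh_worsen": np.full(N_AGE_BANDS, config.srh_worsen_prob),
    }

    years = np.arange(config.start_year, config.start_year + horizon_years + 1)
    c0, c1, cap = config.entry_college_share
    l0, l1, floor = config.entry_lths_share
    college = np.clip(c0 + c1 * (years - config.start_year), None, cap)
    lths = np.clip(l0 + l1 * (years - config.start_year), floor, None)
    hs = 1.0 - college - lths
    schedule = pd.DataFrame(
        {
            "year": years,
            "count": int(round(config.entry_rate * config.population_size)),
            "share_less_than_high_school": lths,
            "share_high_school": hs,
            "share_college_or_higher": college,
            "share_female": 0.5,
            "pre_entry_survival": config.pre_entry_survival,
        }
    )

    entry_prob = np.zeros((3, len(CONDITIONS)))
    for e in range(3):
        for j, cond in enumerate(CONDITIONS):
            # entrants are ~61 years old; average over sexes
            entry_prob[e, j] = 0.5 * (
                condition_probability(config, cond, 61.0, 0, e)
                + condition_probability(config, cond, 61.0, 1, e)
            )

    loghr = np.array([config.condition_mortality_loghr[c] for c in CONDITIONS])
    return TransitionParameters(
        incidence=incidence,
        mortality=mortality,
        condition_mortality_loghr=loghr,
        functional=functional,
        entry_schedule=schedule,
        entry_condition_prob=entry_prob,
        entry_depression_prob=float(
            expit(config.depression_logit[0] + config.depression_logit[1] * 1.0)
        ),
    )


# ---------------------------------------------------------------------------
# survey and claims fixtures
# ---------------------------------------------------------------------------

def _survey_covariates(n, rng, age_low=60, age_high=85, age_slope=0.03,
                       education_shares=(0.35, 0.45, 0.20)):
    ages = np.arange(age_low, age_high + 1)
    w = np.exp(-age_slope * (ages - age_low))
    w /= w.sum()
    df = pd.DataFrame(
        {
            "age": rng.choice(ages, size=n, p=w).astype(float),
            "female": rng.integers(0, 2, size=n).astype(np.int8),
            "education": rng.choice(3, size=n, p=np.asarray(education_shares)).astype(np.int8),
        }
    )
    # comorbidity flags with a mild age gradient, enough signal for recovery
    cfg = default_config(population_size=1)
    for cond in CONDITIONS:
        p = condition_probability(
            cfg, cond, df["age"].to_numpy(), df["female"].to_numpy(), df["education"].to_numpy()
        )
        df[cond] = (rng.random(n) < p).astype(np.int8)
    return df


def generate_cognitive_survey(
    n: int, truth: TruthParameters, seed: int
) -> pd.DataFrame:
    """Cognitive-test survey: correlated binary outcomes via a latent MVN.

    Each record carries covariates (age, sex, education, comorbidities) and
    ten binary outcomes — three test failures (immediate/delayed recall,
    serial sevens) and seven IADL difficulties — generated by thresholding a
    latent multivariate normal at the probit linear predictors.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    R = truth.probit_correlation
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise DataError("probit correlation matrix is not positive definite") from exc
    rng = derive_rng(seed, "cognitive_survey")
    df = _survey_covariates(n, rng, age_low=60, age_high=85)
    X = design_matrix(df, PROBIT_COVARIATES)
    eta = X @ truth.probit_coefficients.to_numpy().T  # (n, 10)
    u = rng.standard_normal((n, len(PROBIT_OUTCOMES))) @ L.T
    outcomes = (eta + u > 0).astype(np.int8)
    for j, name in enumerate(PROBIT_OUTCOMES):
        df[name] = outcomes[:, j]
    return df


def generate_frailty_survey(n: int, truth: TruthParameters, seed: int) -> pd.DataFrame:
    """Community frailty survey fixture (ages >= 65).

    Emulates a field survey that measured a binary frailty phenotype on
    community-dwelling older adults; the phenotype follows the logistic
    truth model over age, sex, education, seven comorbidities, depression,
    and impaired mobility.  The default study size is 1952 records.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    rng = derive_rng(seed, "frailty_survey")
    df = _survey_covariates(n, rng, age_low=65, age_high=94, age_slope=0.05)
    df["depression"] = (rng.random(n) < expit(-2.5 + 0.012 * (df["age"] - 65))).astype(np.int8)
    df["impaired_mobility"] = (
        rng.random(n) < expit(-3.0 + 0.06 * (df["age"] - 65))
    ).astype(np.int8)
    X = design_matrix(df, FRAILTY_COVARIATES)
    p = expit(X @ truth.frailty_logit_coefficients.to_numpy())
    df["frail"] = (rng.random(n) < p).astype(np.int8)
    return df


def expected_monthly_use(truth: TruthParameters, df: pd.DataFrame) -> pd.DataFrame:
    """Truth-implied expected monthly use per service type (no noise/floor)."""
    X = design_matrix(df, COST_COVARIATES)
    out = {}
    for svc in SERVICE_TYPES:
        out[svc] = X @ truth.cost_coefficients.loc[svc].to_numpy()
    return pd.DataFrame(out, index=df.index)


def generate_utilization_claims(n: int, truth: TruthParameters, seed: int) -> pd.DataFrame:
    """Monthly claims fixture: use by service type linked to comorbidity.

    Monthly use is linear in age, sex, the eleven comorbidity flags and the
    comorbidity count, plus Gaussian noise, floored at zero (the intercepts
    are large relative to the noise, so the floor binds with negligible
    probability and least-squares refits recover the truth).
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    rng = derive_rng(seed, "claims")
    df = _survey_covariates(n, rng, age_low=60, age_high=95)
    mu = expected_monthly_use(truth, df)
    for svc in SERVICE_TYPES:
        sd = truth.cost_noise_sd[svc]
        df[svc] = np.maximum(mu[svc].to_numpy() + rng.normal(0.0, sd, size=n), 0.0)
    return df


# ---------------------------------------------------------------------------
# calibration targets
# ---------------------------------------------------------------------------

#: Default target prevalence curves, logistic in age per sex:
#: prevalence(age) = expit(c0 + c1 * (age - 75)).  Shapes follow Japanese
#: epidemiological surveys qualitatively: dementia doubling roughly every
#: five years of age, a flatter MCI curve, frailty rising steadily from 65.
DEFAULT_TARGET_CURVES = {
    "dementia": {"female": (-2.2, 0.13), "male": (-2.5, 0.12)},
    "mci": {"female": (-2.0, 0.03), "male": (-2.0, 0.03)},
    "frailty": {"female": (-2.4, 0.09), "male": (-2.6, 0.09)},
}


@dataclass
class CalibrationTarget:
    """Age-sex target prevalence curves for dementia, MCI, and frailty.

    ``frame`` has columns (sex, age_band, condition, prevalence) covering
    every five-year band per sex and condition.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        req = {"sex", "age_band", "condition", "prevalence"}
        if not req.issubset(self.frame.columns):
            raise DataError(f"target frame must have columns {sorted(req)}")
        p = self.frame["prevalence"].to_numpy(dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise DataError("target prevalence outside [0, 1]")

    def lookup(self, condition: str, sex: str, age_band: str) -> float:
        m = self.frame[
            (self.frame["condition"] == condition)
            & (self.frame["sex"] == sex)
            & (self.frame["age_band"] == age_band)
        ]
        if m.empty:
            raise DataError(
                f"target has no cell for {condition}/{sex}/{age_band}"
            )
        return float(m["prevalence"].iloc[0])

    def overall(self, population: pd.DataFrame, condition: str,
                min_age: float | None = None) -> float:
        """Population-weighted overall target prevalence.

        Weights each (sex, band) target cell by the live population counts,
        optionally restricted to ``age >= min_age``.
        """
        df = population.loc[population["alive"]] if "alive" in population.columns else population
        if min_age is not None:
            df = df.loc[df["age"] >= min_age]
        if df.empty:
            raise DataError("no persons in the requested age range")
        band = np.asarray(AGE_BANDS)[age_band_index(df["age"].to_numpy())]
        sex = np.where(df["female"].to_numpy() == 1, "female", "male")
        counts = pd.DataFrame({"sex": sex, "age_band": band}).value_counts()
        total = counts.sum()
        acc = 0.0
        for (s, b), c in counts.items():
            acc += c * self.lookup(condition, s, b)
        return float(acc / total)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTarget":
        return cls(pd.read_csv(path))


def generate_target_prevalence(
    curve_params: dict | None = None,
    min_band_age: dict | None = None,
) -> CalibrationTarget:
    """Tabulate target prevalence curves over the model's age bands.

    ``curve_params[condition][sex] = (c0, c1)`` defines a logistic-in-age
    curve ``expit(c0 + c1 * (age - 75))`` evaluated at band midpoints.
    ``min_band_age`` restricts a condition's support (frailty targets start
    at 65, the survey's support).
    """
    curves = curve_params if curve_params is not None else DEFAULT_TARGET_CURVES
    min_band_age = min_band_age or {"frailty": 65}
    mid = age_band_midpoint(np.arange(N_AGE_BANDS))
    rows = []
    for condition, per_sex in curves.items():
        lo = min_band_age.get(condition, 60)
        for sex, (c0, c1) in per_sex.items():
            for b in range(N_AGE_BANDS):
                if AGE_BAND_LOWER[b] + 4 < lo:
                    continue
                rows.append(
                    (sex, AGE_BANDS[b], condition, float(expit(c0 + c1 * (mid[b] - 75.0))))
                )
    return CalibrationTarget(
        pd.DataFrame(rows, columns=["sex", "age_band", "condition", "prevalence"])
    )
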