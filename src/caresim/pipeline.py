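"""End-to-end projection pipeline.

One run of the pipeline emulates the full study design on synthetic data:

1. generate survey/claims fixtures and fit the classification and cost
   models (multivariate probit of cognitive impairment, logistic frailty
   model, monthly-use regressions);
2. generate the baseline population (aged 60+) and the half-year transition
   parameter tables, and evolve the population to the horizon with annual
   entry cohorts at ages 60-62;
3. at the baseline snapshot, calibrate the dementia/MCI and frailty
   probability cutoffs to the target prevalence curves; hold them fixed
   over the projection;
4. classify every 3-year snapshot, tabulate prevalence (by sex and the
   age groups >=60, 60-74, >=75), build period life tables by sex, apply
   the Sullivan partition for dementia and frailty, and cost the population
   (health care, formal long-term care, informal care).

Model estimation can be shared across bootstrap iterations (coefficients
held fixed) while population generation, transitions and classification
randomness are redrawn per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import derive_int_seed, derive_rng
from .cognition import (
    CognitionThresholds,
    ProbitModel,
    calibrate_thresholds,
    classify_cognition,
    fit_cognitive_probit,
    predict_impairment_probability,
)
from .costs import CostParameters, aggregate_costs, annual_costs, assign_dependency_level, fit_healthcare_use
from .engine import PopulationState, Trajectory, simulate
from .errors import ConfigurationError, DataError
from .frailty import (
    FRAILTY_MIN_AGE,
    FrailtyThreshold,
    LogisticModel,
    calibrate_frailty_threshold,
    classify_frailty,
    fit_frailty_logit,
    predict_frailty_probability,
)
from .lifetable import build_period_life_table, sullivan_partition
from .synthetic import (
    CalibrationTarget,
    GeneratorConfig,
    TruthParameters,
    default_truth,
    generate_baseline_population,
    generate_cognitive_survey,
    generate_frailty_survey,
    generate_target_prevalence,
    generate_transition_parameters,
    generate_utilization_claims,
)

__all__ = [
    "PipelineConfig",
    "FittedModels",
    "RunResult",
    "fit_models",
    "calibrate_classifiers",
    "classify_snapshot",
    "run_once",
    "AGE_GROUPS",
]

#: Reporting age groups of the prevalence tables.
AGE_GROUPS = {"60plus": (60, np.inf), "60_74": (60, 75), "75plus": (75, np.inf)}
PREVALENCE_CONDITIONS = ("mci", "dementia", "frailty", "dementia_and_frailty")


@dataclass
class PipelineConfig:
    """Configuration of a full projection run."""

    generator: GeneratorConfig
    truth: TruthParameters = field(default_factory=default_truth)
    horizon_years: int = 27
    report_interval: int = 3
    presentation_interval: int = 9
    cognitive_survey_n: int = 6000
    frailty_survey_n: int = 1952
    claims_n: int = 6000
    battery_rule: int = 2
    life_table_width: int = 5
    life_table_terminal_age: int = 95
    life_table_start_age: int = 65
    target_curves: dict | None = None
    n_bootstrap: int = 50
    # Persons sharing a covariate pattern share a predicted probability, so
    # attainable prevalence moves in tie-block jumps; this is the practical
    # tolerance for snapping to the nearest attainable share.
    calibration_tolerance: float = 0.01

    def __post_init__(self):
        if self.horizon_years % self.report_interval != 0:
            raise ConfigurationError("horizon must be divisible by the report interval")
        if self.presentation_interval % self.report_interval != 0:
            raise ConfigurationError(
                "presentation interval must be a multiple of the report interval"
            )

    @property
    def presentation_years(self) -> list:
        y0 = self.generator.start_year
        return list(range(y0, y0 + self.horizon_years + 1, self.presentation_interval))


@dataclass
class FittedModels:
    """Estimated classification and cost models, shared across iterations."""

    probit: ProbitModel
    frailty: LogisticModel
    cost: CostParameters


@dataclass
class RunResult:
    """Tables produced by one pipeline run."""

    prevalence: pd.DataFrame
    life_expectancy: pd.DataFrame
    costs_total: pd.DataFrame
    costs_per_capita: pd.DataFrame
    thresholds: pd.DataFrame
    trajectory: Trajectory | None = None

    def tables(self) -> dict:
        return {
            "prevalence": self.prevalence,
            "life_expectancy": self.life_expectancy,
            "costs_total": self.costs_total,
            "costs_per_capita": self.costs_per_capita,
            "thresholds": self.thresholds,
        }


def fit_models(config: PipelineConfig, seed: int) -> FittedModels:
    """Generate the survey/claims fixtures and estimate all models."""
    truth = config.truth
    cog = generate_cognitive_survey(
        config.cognitive_survey_n, truth, derive_int_seed(seed, "cognitive")
    )
    probit = fit_cognitive_probit(cog)
    fra = generate_frailty_survey(
        config.frailty_survey_n, truth, derive_int_seed(seed, "frailty")
    )
    frailty = fit_frailty_logit(fra)
    claims = generate_utilization_claims(
        config.claims_n, truth, derive_int_seed(seed, "claims")
    )
    coef, _se = fit_healthcare_use(claims)
    return FittedModels(probit=probit, frailty=frailty, cost=CostParameters(coef))


def _predict_probabilities(models: FittedModels, persons, battery_rule: int):
    p_fail, p_joint = predict_impairment_probability(
        models.probit, persons, battery_rule=battery_rule
    )
    p_frail = predict_frailty_probability(models.frailty, persons)
    return p_fail, p_joint, p_frail


def calibrate_classifiers(
    models: FittedModels,
    baseline: PopulationState,
    targets: CalibrationTarget,
    battery_rule: int = 2,
    tol: float = 0.01,
) -> tuple[CognitionThresholds, FrailtyThreshold]:
    """Calibrate cutoffs so baseline prevalence matches the target curves.

    The dementia/MCI targets are overall population-weighted prevalences of
    the target curves over the live 60+ population; the frailty target is
    weighted over the 65+ population (the survey's support).
    """
    alive = baseline.alive_frame()
    p_fail, p_joint, _ = _predict_probabilities(models, alive, battery_rule)
    cog = calibrate_thresholds(
        p_fail,
        p_joint,
        target_dementia=targets.overall(alive, "dementia"),
        target_mci=targets.overall(alive, "mci"),
        tol=tol,
    )
    eligible = alive[alive["age"] >= FRAILTY_MIN_AGE]
    p_frail = predict_frailty_probability(models.frailty, eligible)
    frail = calibrate_frailty_threshold(
        p_frail,
        targets.overall(alive, "frailty", min_age=FRAILTY_MIN_AGE),
        tol=tol,
    )
    return cog, frail


def classify_snapshot(
    state: PopulationState,
    models: FittedModels,
    cog_thresholds: CognitionThresholds,
    frailty_threshold: FrailtyThreshold,
    battery_rule: int = 2,
) -> PopulationState:
    """Label dementia state, frailty and dependency on a snapshot (in place)."""
    frame = state.frame
    alive_mask = frame["alive"].to_numpy()
    alive = frame.loc[alive_mask]
    if len(alive) == 0:
        return state
    p_fail, p_joint, p_frail = _predict_probabilities(models, alive, battery_rule)
    dementia = classify_cognition(p_fail, p_joint, cog_thresholds)
    frail = classify_frailty(p_frail, frailty_threshold, age=alive["age"].to_numpy())
    frame.loc[alive_mask, "dementia_state"] = dementia
    frame.loc[alive_mask, "frail"] = frail
    frame.loc[alive_mask, "dependency"] = assign_dependency_level(frame.loc[alive_mask])
    return state


def _prevalence_rows(state: PopulationState) -> list:
    alive = state.alive_frame()
    rows = []
    for s, sex in ((0, "male"), (1, "female")):
        part_sex = alive[alive["female"] == s]
        for group, (lo, hi) in AGE_GROUPS.items():
            part = part_sex[(part_sex["age"] >= lo) & (part_sex["age"] < hi)]
            pop = len(part)
            dem = part["dementia_state"].to_numpy() == 2
            mci = part["dementia_state"].to_numpy() == 1
            fra = part["frail"].to_numpy() == 1
            counts = {
                "mci": int(mci.sum()),
                "dementia": int(dem.sum()),
                "frailty": int(fra.sum()),
                "dementia_and_frailty": int((dem & fra).sum()),
            }
            for cond in PREVALENCE_CONDITIONS:
                rows.append(
                    {
                        "year": state.year,
                        "sex": sex,
                        "age_group": group,
                        "condition": cond,
                        "count": counts[cond],
                        "population": pop,
                        "proportion_pct": 100.0 * counts[cond] / pop if pop else np.nan,
                    }
                )
    return rows


def _prevalence_for_table(alive: pd.DataFrame, table_frame: pd.DataFrame, flag: np.ndarray):
    """Age-specific prevalence aligned with life-table rows (forward-filled
    where an interval holds no simulated person)."""
    ages = alive["age"].to_numpy()
    prev = np.full(len(table_frame), np.nan)
    for i, (a, w) in enumerate(zip(table_frame["age"], table_frame["width"])):
        hi = a + w if np.isfinite(w) else np.inf
        mask = (ages >= a) & (ages < hi)
        if mask.any():
            prev[i] = float(flag[mask].mean())
    # forward-fill from younger intervals, then backward as a last resort
    last = np.nan
    for i in range(len(prev)):
        if np.isnan(prev[i]):
            prev[i] = last
        else:
            last = prev[i]
    if np.isnan(prev).any():
        prev = pd.Series(prev).bfill().fillna(0.0).to_numpy()
    return np.clip(prev, 0.0, 1.0)


def _life_expectancy_rows(
    config: PipelineConfig, trajectory: Trajectory, year: int
) -> list:
    exp = trajectory.mortality_experience
    max_year = int(exp["year"].max())
    interval = config.report_interval
    if year + interval - 1 <= max_year:
        window = list(range(year, year + interval))
    else:
        window = list(range(year - interval, year))
    snapshot = trajectory.snapshot_at(year)
    alive = snapshot.alive_frame()
    rows = []
    for s, sex in ((0, "male"), (1, "female")):
        table = build_period_life_table(
            exp,
            stratum={"female": s},
            years=window,
            start_age=config.life_table_start_age,
            width=config.life_table_width,
            terminal_age=config.life_table_terminal_age,
        )
        part = alive[alive["female"] == s]
        for condition, flag in (
            ("dementia", part["dementia_state"].to_numpy() == 2),
            ("frailty", part["frail"].to_numpy() == 1),
        ):
            prev = _prevalence_for_table(part, table.frame, flag)
            sle = sullivan_partition(table, prev, condition=condition)
            rows.append(
                {
                    "year": year,
                    "sex": sex,
                    "condition": condition,
                    "life_expectancy": sle.total_ex,
                    "years_with": sle.years_with,
                    "years_without": sle.years_without,
                }
            )
    return rows


def run_once(
    config: PipelineConfig,
    seed: int,
    fitted: FittedModels | None = None,
    keep_trajectory: bool = False,
) -> RunResult:
    """Execute one full projection run with the given master seed."""
    if fitted is None:
        fitted = fit_models(config, derive_int_seed(seed, "fit"))
    targets = generate_target_prevalence(config.target_curves)

    gcfg = replace(config.generator, seed=derive_int_seed(seed, "population"))
    baseline_frame = generate_baseline_population(gcfg)
    params = generate_transition_parameters(gcfg, horizon_years=config.horizon_years + 1)
    baseline = PopulationState(baseline_frame, float(gcfg.start_year))

    trajectory = simulate(
        baseline,
        params,
        config.horizon_years,
        rng=derive_rng(seed, "engine"),
        report_interval=config.report_interval,
    )

    cog_thr, frail_thr = calibrate_classifiers(
        fitted,
        trajectory.snapshots[0],
        targets,
        battery_rule=config.battery_rule,
        tol=config.calibration_tolerance,
    )
    thresholds = pd.DataFrame(
        [
            {
                "theta_dementia": cog_thr.theta_dementia,
                "theta_mci": cog_thr.theta_mci,
                "theta_frail": frail_thr.theta_frail,
                "achieved_dementia": cog_thr.achieved_dementia,
                "achieved_mci": cog_thr.achieved_mci,
                "achieved_frailty": frail_thr.achieved_prevalence,
            }
        ]
    )

    prevalence_rows = []
    for snap in trajectory.snapshots:
        classify_snapshot(
            snap, fitted, cog_thr, frail_thr, battery_rule=config.battery_rule
        )
        prevalence_rows.extend(_prevalence_rows(snap))
    prevalence = pd.DataFrame(prevalence_rows)

    le_rows = []
    cost_total_parts = []
    cost_pc_parts = []
    for year in config.presentation_years:
        le_rows.extend(_life_expectancy_rows(config, trajectory, year))
        snap = trajectory.snapshot_at(year)
        alive = snap.alive_frame()
        costed = annual_costs(alive, fitted.cost, rng=derive_rng(seed, "costs", year))
        agg = aggregate_costs(costed, persons=alive)
        cost_total_parts.append(agg["totals"].assign(year=year))
        cost_pc_parts.append(agg["per_capita"].assign(year=year))

    return RunResult(
        prevalence=prevalence,
        life_expectancy=pd.DataFrame(le_rows),
        costs_total=pd.concat(cost_total_parts, ignore_index=True),
        costs_per_capita=pd.concat(cost_pc_parts, ignore_index=True),
        thresholds=thresholds,
        trajectory=trajectory if keep_trajectory else None,
    )
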