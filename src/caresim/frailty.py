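"""Logistic frailty model: fitting, prediction, threshold calibration.

Frailty enters the simulation as a phenotype-style binary state: a logistic
regression of the surveyed frailty phenotype on age, sex, educational
attainment, seven comorbid conditions, depression, and impaired mobility in
daily living is fitted to a community survey (the shipped fixture emulates a
1952-person survey of people aged 65 and older), the fitted model
extrapolates a frailty probability for every simulated person, and a cutoff
calibrated to an external target prevalence turns the probability into a
label.  Frailty is re-evaluated from current covariates at every reporting
period, so — unlike the non-reversible chronic conditions — the label can
fluctuate; persons younger than 65 (outside the survey's support) are never
labelled frail.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .calibration import threshold_for_prevalence
from .core import FRAILTY_COVARIATES, design_matrix
from .errors import DataError, FitFailureError

__all__ = [
    "LogisticModel",
    "FrailtyThreshold",
    "fit_frailty_logit",
    "predict_frailty_probability",
    "calibrate_frailty_threshold",
    "classify_frailty",
    "FRAILTY_MIN_AGE",
]

FRAILTY_MIN_AGE = 65.0


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit with standard errors."""

    covariates: tuple
    coefficients: pd.Series
    standard_errors: pd.Series
    log_likelihood: float
    n_obs: int

    def __post_init__(self):
        if list(self.coefficients.index) != list(self.covariates):
            raise DataError("coefficient vector does not match covariate set")

    def to_json(self, path=None) -> str:
        payload = {
            "covariates": list(self.covariates),
            "coefficients": self.coefficients.to_dict(),
            "standard_errors": self.standard_errors.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "LogisticModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        covs = tuple(payload["covariates"])
        return cls(
            covariates=covs,
            coefficients=pd.Series(payload["coefficients"]).loc[list(covs)],
            standard_errors=pd.Series(payload["standard_errors"]).loc[list(covs)],
            log_likelihood=payload["log_likelihood"],
            n_obs=payload["n_obs"],
        )


@dataclass
class FrailtyThreshold:
    """Calibrated frailty cutoff and the prevalence it achieves."""

    theta_frail: float
    achieved_prevalence: float = float("nan")

    def __post_init__(self):
        if not 0.0 <= self.theta_frail <= 1.0:
            raise DataError(f"theta_frail must be in [0, 1], got {self.theta_frail}")


def fit_frailty_logit(
    survey: pd.DataFrame, covariates=FRAILTY_COVARIATES, outcome: str = "frail"
) -> LogisticModel:
    """Fit the logistic frailty model by maximum likelihood."""
    if len(survey) < 200:
        raise DataError(f"survey too small ({len(survey)} records; need >= 200)")
    y = survey[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise FitFailureError("frailty outcome is degenerate (one class only)")
    X = design_matrix(survey, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise FitFailureError(f"frailty logit fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise FitFailureError("frailty logit has non-finite standard errors (separation?)")
    return LogisticModel(
        covariates=tuple(covariates),
        coefficients=pd.Series(res.params, index=list(covariates)),
        standard_errors=pd.Series(res.bse, index=list(covariates)),
        log_likelihood=float(res.llf),
        n_obs=len(survey),
    )


def predict_frailty_probability(model: LogisticModel, persons) -> np.ndarray:
    """Inverse-logit of the linear predictor, in (0, 1).

    ``impaired_mobility`` is mapped from the ADL/IADL state when not given
    explicitly (see :func:`caresim.core.impaired_mobility`).
    """
    single = isinstance(persons, pd.Series)
    if single:
        persons = persons.to_frame().T
    X = design_matrix(persons, model.covariates)
    p = expit(X @ model.coefficients.to_numpy())
    return float(p[0]) if single else p


def calibrate_frailty_threshold(
    probabilities,
    target_prevalence: float,
    tol: float = 1e-4,
    denominator: int | None = None,
) -> FrailtyThreshold:
    """Cutoff whose labelled share matches the target prevalence.

    ``probabilities`` are the predicted frailty probabilities of the
    eligible (age >= 65) persons; the achieved share refers to
    ``denominator`` persons when the target is expressed against a larger
    population.
    """
    theta, achieved = threshold_for_prevalence(
        probabilities, target_prevalence, tol=tol, denominator=denominator
    )
    return FrailtyThreshold(theta_frail=theta, achieved_prevalence=achieved)


def classify_frailty(probability, threshold: FrailtyThreshold, age=None) -> np.ndarray:
    """Frail iff probability >= theta_frail (and age >= 65 when ages given)."""
    p = np.atleast_1d(np.asarray(probability, dtype=float))
    frail = (p >= threshold.theta_frail).astype(np.int8)
    if age is not None:
        frail = np.where(np.atleast_1d(age) >= FRAILTY_MIN_AGE, frail, np.int8(0)).astype(
            np.int8
        )
    return frail
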