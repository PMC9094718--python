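"""Multivariate probit model of cognitive impairment and its calibration.

Dementia status in the simulation is operationalised the way social-survey
algorithms in the Health-and-Retirement-Study tradition do it: a person's
probability of *failing the cognitive battery* (immediate/delayed word
recall and serial sevens) and the *joint* probability of failing the battery
while reporting at least one of seven IADL difficulties are computed from a
multivariate probit — ten correlated binary outcomes regressed on age, sex,
educational attainment and multi-comorbidity through a latent multivariate
normal.  Probability cutoffs on those two quantities are then calibrated so
the modelled prevalence of dementia and of mild cognitive impairment (MCI)
matches external target prevalence curves.

Classification rule (configurable battery rule, default >= 2 of 3 tests
failed):

* dementia  — joint probability (failure and >= 1 IADL difficulty) >= theta_dementia
* MCI       — battery-failure probability >= theta_mci, and not dementia
* normal    — otherwise
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm, qmc

from .calibration import threshold_for_prevalence
from .core import PROBIT_COVARIATES, design_matrix
from .errors import DataError, FitFailureError
from .synthetic import PROBIT_OUTCOMES, COGNITIVE_TESTS

__all__ = [
    "ProbitModel",
    "CognitionThresholds",
    "bvn_cdf",
    "fit_cognitive_probit",
    "predict_impairment_probability",
    "calibrate_thresholds",
    "classify_cognition",
]

N_TESTS = len(COGNITIVE_TESTS)


# ---------------------------------------------------------------------------
# bivariate normal orthant probability (Owen, 1956)
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorised over ``h`` and ``k`` via Owen's T function; used inside the
    pairwise latent-correlation root search where a fast vectorised
    evaluation matters.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if abs(rho) < 1e-13:
        return norm.cdf(h) * norm.cdf(k)
    if rho > 1 - 1e-12:
        return norm.cdf(np.minimum(h, k))
    if rho < -1 + 1e-12:
        return np.clip(norm.cdf(h) + norm.cdf(k) - 1.0, 0.0, None)
    s = np.sqrt(1.0 - rho * rho)
    eps = 1e-14
    hh = np.where(np.abs(h) < eps, eps, h)
    kk = np.where(np.abs(k) < eps, eps, k)
    a_h = (kk - rho * hh) / (hh * s)
    a_k = (hh - rho * kk) / (kk * s)
    beta = np.where((hh * kk < 0) | ((hh * kk == 0) & (hh + kk < 0)), 0.5, 0.0)
    val = 0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(hh, a_h) - owens_t(kk, a_k) - beta
    return np.clip(val, 0.0, 1.0)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class ProbitModel:
    """Fitted multivariate probit: per-outcome coefficients plus the latent
    outcome correlation matrix (pairwise/composite estimate)."""

    outcomes: tuple
    covariates: tuple
    coefficients: pd.DataFrame      # outcomes x covariates
    standard_errors: pd.DataFrame   # outcomes x covariates
    correlation: np.ndarray         # (n_outcomes, n_outcomes)
    log_likelihood: float
    n_obs: int

    def __post_init__(self):
        self.correlation = np.asarray(self.correlation, dtype=float)
        k = len(self.outcomes)
        if self.correlation.shape != (k, k):
            raise DataError("correlation matrix shape mismatch")
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-10):
            raise DataError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-10):
            raise DataError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.correlation).min() <= 0:
            raise DataError("correlation matrix must be positive definite")

    def exchangeable_rho(self) -> float | None:
        """Common off-diagonal correlation, or None if not exchangeable."""
        R = self.correlation
        off = R[~np.eye(len(R), dtype=bool)]
        if off.size == 0:
            return 0.0
        if off.max() - off.min() < 1e-8:
            return float(off.mean())
        return None

    def to_json(self, path=None) -> str:
        payload = {
            "outcomes": list(self.outcomes),
            "covariates": list(self.covariates),
            "coefficients": self.coefficients.to_dict(orient="index"),
            "standard_errors": self.standard_errors.to_dict(orient="index"),
            "correlation": self.correlation.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ProbitModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        outcomes = tuple(payload["outcomes"])
        covs = tuple(payload["covariates"])
        coef = pd.DataFrame.from_dict(payload["coefficients"], orient="index").loc[
            list(outcomes), list(covs)
        ]
        se = pd.DataFrame.from_dict(payload["standard_errors"], orient="index").loc[
            list(outcomes), list(covs)
        ]
        return cls(
            outcomes=outcomes,
            covariates=covs,
            coefficients=coef,
            standard_errors=se,
            correlation=np.asarray(payload["correlation"]),
            log_likelihood=payload["log_likelihood"],
            n_obs=payload["n_obs"],
        )


@dataclass
class CognitionThresholds:
    """Calibrated probability cutoffs for the dementia and MCI labels."""

    theta_dementia: float
    theta_mci: float
    achieved_dementia: float = float("nan")
    achieved_mci: float = float("nan")

    def __post_init__(self):
        for name in ("theta_dementia", "theta_mci"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.theta_dementia < self.theta_mci:
            # The two cutoffs act on different probabilities (joint vs
            # marginal failure), so a reversed ordering does not make the
            # labels inconsistent — but it is unusual, so flag it.
            warnings.warn(
                "theta_dementia < theta_mci: dementia cutoff (on the joint "
                "probability) is below the MCI cutoff (on the failure "
                "probability)",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _nearest_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w.min() > floor:
        np.fill_diagonal(R, 1.0)
        return R
    w = np.clip(w, floor, None)
    R = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _pairwise_rho(a: np.ndarray, b: np.ndarray, p11: float) -> float:
    """Latent correlation matching the observed pairwise agreement rate.

    Solves ``mean_i bvn_cdf(a_i, b_i, rho) = p11`` where ``a``/``b`` are the
    two outcomes' fitted linear predictors.
    """

    def g(rho):
        return float(np.mean(bvn_cdf(a, b, rho))) - p11

    lo, hi = -0.98, 0.98
    glo, ghi = g(lo), g(hi)
    if glo >= 0:
        return lo
    if ghi <= 0:
        return hi
    return float(brentq(g, lo, hi, xtol=1e-6))


def fit_cognitive_probit(
    survey: pd.DataFrame,
    outcomes=PROBIT_OUTCOMES,
    covariates=PROBIT_COVARIATES,
    corr_subsample: int = 2000,
) -> ProbitModel:
    """Fit the multivariate probit by outcome-wise ML plus pairwise correlation.

    Each outcome is fitted by maximum likelihood (univariate probit); the
    latent correlation matrix is then estimated pairwise by matching the
    model-implied joint success probability to the observed one, and
    projected to the nearest positive-definite correlation matrix.
    """
    if len(survey) < 200:
        raise DataError(f"survey too small ({len(survey)} records; need >= 200)")
    X = design_matrix(survey, covariates)
    Y = np.column_stack([survey[o].to_numpy(dtype=float) for o in outcomes])

    coefs, ses = [], []
    loglik = 0.0
    for j, name in enumerate(outcomes):
        y = Y[:, j]
        if y.min() == y.max():
            raise FitFailureError(
                f"outcome {name!r} is degenerate (all values {y[0]:.0f})"
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Probit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises various separation errors
            raise FitFailureError(f"probit fit failed for outcome {name!r}: {exc}") from exc
        if not np.all(np.isfinite(res.bse)):
            raise FitFailureError(
                f"probit fit for outcome {name!r} has non-finite standard errors "
                "(possible separation)"
            )
        coefs.append(res.params)
        ses.append(res.bse)
        loglik += float(res.llf)

    coef = pd.DataFrame(coefs, index=list(outcomes), columns=list(covariates))
    se = pd.DataFrame(ses, index=list(outcomes), columns=list(covariates))

    # pairwise latent correlation on a deterministic subsample (speed)
    k = len(outcomes)
    idx = np.linspace(0, len(survey) - 1, min(corr_subsample, len(survey))).astype(int)
    eta = X @ coef.to_numpy().T
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            p11 = float(np.mean(Y[:, i] * Y[:, j]))
            rho = _pairwise_rho(eta[idx, i], eta[idx, j], p11)
            R[i, j] = R[j, i] = rho
    R = _nearest_correlation(R)

    return ProbitModel(
        outcomes=tuple(outcomes),
        covariates=tuple(covariates),
        coefficients=coef,
        standard_errors=se,
        correlation=R,
        log_likelihood=loglik,
        n_obs=len(survey),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _battery_probability(p_tests: np.ndarray, rule: int) -> np.ndarray:
    """P(at least ``rule`` of the tests failed), tests independent given
    ``p_tests`` along the last axis (enumeration over the 2^m patterns)."""
    m = p_tests.shape[-1]
    out = np.zeros(p_tests.shape[:-1])
    for pattern in product((0, 1), repeat=m):
        if sum(pattern) < rule:
            continue
        term = np.ones_like(out)
        for j, bit in enumerate(pattern):
            pj = p_tests[..., j]
            term = term * (pj if bit else (1.0 - pj))
        out += term
    return out


def predict_impairment_probability(
    model: ProbitModel,
    persons: pd.DataFrame,
    battery_rule: int = 2,
    method: str = "auto",
    n_qmc: int = 512,
    gh_nodes: int = 41,
    seed: int = 20160,
    chunk: int = 4096,
):
    """Per-person impairment probabilities from the latent-normal model.

    Returns ``(p_fail, p_joint)``: the probability of failing the cognitive
    battery (>= ``battery_rule`` of the tests below cutoff), and the joint
    probability of battery failure together with at least one IADL
    difficulty.  Joint orthant probabilities are computed by Gauss-Hermite
    quadrature under the one-factor (exchangeable-correlation)
    representation when available, and by scrambled-Sobol quasi-Monte Carlo
    otherwise (``method='qmc'`` forces the latter).

    Covariate values outside the fitted support produce a warning and an
    extrapolated prediction.
    """
    single = isinstance(persons, pd.Series)
    if single:
        persons = persons.to_frame().T
    X = design_matrix(persons, model.covariates)
    if "age" in persons.columns:
        ages = persons["age"].to_numpy(dtype=float)
        if (ages < 50).any() or (ages > 110).any():
            warnings.warn("age outside fitted support; prediction extrapolates")
    eta = X @ model.coefficients.to_numpy().T  # (n, k)
    k = len(model.outcomes)
    n = len(persons)
    rho = model.exchangeable_rho() if method in ("auto", "quadrature") else None
    if method == "quadrature" and (rho is None or rho < 0):
        raise DataError("quadrature method requires exchangeable non-negative correlation")

    p_fail = np.empty(n)
    p_joint = np.empty(n)
    if rho is not None and rho >= 0.0:
        # one-factor representation: u_j = sqrt(rho) Z + sqrt(1-rho) e_j
        x_gh, w_gh = np.polynomial.hermite.hermgauss(gh_nodes)
        z = np.sqrt(2.0) * x_gh
        wt = w_gh / np.sqrt(np.pi)
        sr, sc = np.sqrt(rho), np.sqrt(1.0 - rho)
        for lo in range(0, n, chunk):
            e = eta[lo : lo + chunk]  # (c, k)
            pz = norm.cdf((e[:, None, :] + sr * z[None, :, None]) / sc)  # (c, m, k)
            fail_z = _battery_probability(pz[..., :N_TESTS], battery_rule)
            any_iadl_z = 1.0 - np.prod(1.0 - pz[..., N_TESTS:], axis=-1)
            p_fail[lo : lo + chunk] = fail_z @ wt
            p_joint[lo : lo + chunk] = (fail_z * any_iadl_z) @ wt
    else:
        L = np.linalg.cholesky(model.correlation)
        m = int(2 ** np.ceil(np.log2(max(n_qmc, 16))))
        sob = qmc.Sobol(d=k, scramble=True, seed=seed)
        u = np.clip(sob.random(m), 1e-12, 1 - 1e-12)
        Z = norm.ppf(u) @ L.T  # (m, k)
        for lo in range(0, n, max(chunk // 8, 64)):
            e = eta[lo : lo + max(chunk // 8, 64)]
            ind = (e[:, None, :] + Z[None, :, :]) > 0  # (c, m, k)
            fails = ind[..., :N_TESTS].sum(axis=-1) >= battery_rule
            any_iadl = ind[..., N_TESTS:].any(axis=-1)
            p_fail[lo : lo + len(e)] = fails.mean(axis=1)
            p_joint[lo : lo + len(e)] = (fails & any_iadl).mean(axis=1)

    p_fail = np.clip(p_fail, 0.0, 1.0)
    p_joint = np.clip(np.minimum(p_joint, p_fail), 0.0, 1.0)
    if single:
        return float(p_fail[0]), float(p_joint[0])
    return p_fail, p_joint


# ---------------------------------------------------------------------------
# calibration and classification
# ---------------------------------------------------------------------------

def calibrate_thresholds(
    p_fail: np.ndarray,
    p_joint: np.ndarray,
    target_dementia: float,
    target_mci: float,
    tol: float = 1e-4,
) -> CognitionThresholds:
    """Choose cutoffs so modelled dementia and MCI prevalence match targets.

    The dementia cutoff acts on the joint probability; the MCI cutoff acts
    on the battery-failure probability among persons not labelled dementia.
    Both searches resolve to order statistics of the respective probability
    arrays (exact to person granularity; see :mod:`caresim.calibration`).
    """
    p_fail = np.asarray(p_fail, dtype=float)
    p_joint = np.asarray(p_joint, dtype=float)
    if p_fail.shape != p_joint.shape:
        raise DataError("probability arrays must have equal length")
    n = len(p_fail)
    theta_d, ach_d = threshold_for_prevalence(p_joint, target_dementia, tol=tol)
    dementia = p_joint >= theta_d
    theta_m, ach_m = threshold_for_prevalence(
        p_fail[~dementia], target_mci, tol=tol, denominator=n
    )
    return CognitionThresholds(
        theta_dementia=theta_d,
        theta_mci=theta_m,
        achieved_dementia=ach_d,
        achieved_mci=ach_m,
    )


def classify_cognition(p_fail, p_joint, thresholds: CognitionThresholds) -> np.ndarray:
    """Label each person 0=normal, 1=MCI, 2=dementia (deterministic)."""
    p_fail = np.atleast_1d(np.asarray(p_fail, dtype=float))
    p_joint = np.atleast_1d(np.asarray(p_joint, dtype=float))
    out = np.zeros(p_fail.shape, dtype=np.int8)
    dementia = p_joint >= thresholds.theta_dementia
    mci = ~dementia & (p_fail >= thresholds.theta_mci)
    out[dementia] = 2
    out[mci] = 1
    return out
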