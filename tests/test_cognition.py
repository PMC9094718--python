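"""Multivariate probit: orthant probabilities, fitting, calibration."""

import numpy as np
import pandas as pd
import pytest
from itertools import product
from scipy.stats import multivariate_normal, norm

from caresim import (
    CalibrationError,
    CognitionThresholds,
    FitFailureError,
    ProbitModel,
    calibrate_thresholds,
    classify_cognition,
    fit_cognitive_probit,
    generate_cognitive_survey,
    predict_impairment_probability,
)
from caresim.cognition import bvn_cdf, N_TESTS
from caresim.core import PROBIT_COVARIATES
from caresim.synthetic import PROBIT_OUTCOMES, TruthParameters

from conftest import make_population


def make_model(coef_value=0.0, rho=0.0):
    k = len(PROBIT_OUTCOMES)
    coef = pd.DataFrame(
        coef_value, index=list(PROBIT_OUTCOMES), columns=list(PROBIT_COVARIATES)
    )
    if np.isscalar(coef_value):
        coef.loc[:, :] = 0.0
        coef["const"] = coef_value
    R = np.full((k, k), rho)
    np.fill_diagonal(R, 1.0)
    return ProbitModel(
        outcomes=tuple(PROBIT_OUTCOMES),
        covariates=tuple(PROBIT_COVARIATES),
        coefficients=coef,
        standard_errors=coef * 0.0 + 1.0,
        correlation=R,
        log_likelihood=0.0,
        n_obs=100,
    )


def enumerate_battery_and_joint(marginals, rule=2):
    """Independent-outcomes oracle: enumerate all 2^10 outcome patterns."""
    k = len(marginals)
    p_fail = 0.0
    p_joint = 0.0
    for pattern in product((0, 1), repeat=k):
        prob = 1.0
        for p, bit in zip(marginals, pattern):
            prob *= p if bit else (1 - p)
        fails = sum(pattern[:N_TESTS]) >= rule
        any_iadl = any(pattern[N_TESTS:])
        p_fail += prob * fails
        p_joint += prob * (fails and any_iadl)
    return p_fail, p_joint


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.8, -0.3, 0.0, 0.3, 0.9])
    def test_against_scipy_mvn(self, rho):
        grid = [-2.0, -0.5, 0.0, 0.7, 1.9]
        cov = [[1.0, rho], [rho, 1.0]]
        for h in grid:
            for k in grid:
                expected = multivariate_normal.cdf([h, k], mean=[0, 0], cov=cov,
                                                   abseps=1e-10, releps=1e-10)
                assert abs(float(bvn_cdf(h, k, rho)) - expected) < 1e-8


class TestPrediction:
    def test_independent_null_model_matches_enumeration(self):
        # zero coefficients, independence: every outcome rate 1/2
        model = make_model(0.0, rho=0.0)
        person = make_population(1).iloc[0]
        p_fail, p_joint = predict_impairment_probability(model, person)
        exp_fail, exp_joint = enumerate_battery_and_joint([0.5] * 10)
        assert abs(p_fail - exp_fail) < 1e-9
        assert abs(p_joint - exp_joint) < 1e-9
        assert abs(exp_fail - 0.5) < 1e-12  # 2-of-3 at rate 1/2

    def test_nonuniform_marginals_match_enumeration(self):
        model = make_model(0.0, rho=0.0)
        model.coefficients["const"] = np.linspace(-1.0, 0.8, 10)
        persons = make_population(3)
        p_fail, p_joint = predict_impairment_probability(model, persons)
        marg = norm.cdf(model.coefficients["const"].to_numpy())
        exp_fail, exp_joint = enumerate_battery_and_joint(list(marg))
        np.testing.assert_allclose(p_fail, exp_fail, atol=1e-9)
        np.testing.assert_allclose(p_joint, exp_joint, atol=1e-9)

    def test_quadrature_matches_qmc_with_correlation(self):
        model = make_model(0.0, rho=0.3)
        model.coefficients["const"] = np.linspace(-1.2, 0.5, 10)
        model.coefficients["age_c"] = 0.5
        persons = make_population(40)
        f_quad, j_quad = predict_impairment_probability(model, persons, method="quadrature")
        f_qmc, j_qmc = predict_impairment_probability(model, persons, method="qmc",
                                                      n_qmc=4096)
        assert np.max(np.abs(f_quad - f_qmc)) < 0.02
        assert np.max(np.abs(j_quad - j_qmc)) < 0.02

    def test_limiting_case_probabilities_approach_one(self):
        model = make_model(0.0, rho=0.3)
        model.coefficients["age_c"] = 50.0  # overwhelming age effect
        old = make_population(1, age_low=95, age_high=95)
        p_fail, p_joint = predict_impairment_probability(model, old.iloc[0])
        assert p_fail > 0.999 and p_joint > 0.999

    def test_joint_never_exceeds_marginal(self):
        model = make_model(0.0, rho=0.4)
        rng = np.random.default_rng(3)
        model.coefficients.loc[:, :] = rng.normal(0, 0.5, model.coefficients.shape)
        persons = make_population(200, rng)
        p_fail, p_joint = predict_impairment_probability(model, persons)
        assert (p_joint <= p_fail + 1e-12).all()


class TestFitting:
    def test_null_truth_recovers_zero_slopes(self, truth):
        zero = truth.probit_coefficients * 0.0
        t = TruthParameters(
            probit_coefficients=zero,
            probit_correlation=np.eye(10),
            frailty_logit_coefficients=truth.frailty_logit_coefficients,
            cost_coefficients=truth.cost_coefficients,
        )
        survey = generate_cognitive_survey(3000, t, seed=4)
        model = fit_cognitive_probit(survey)
        slopes = model.coefficients.drop(columns="const")
        ses = model.standard_errors.drop(columns="const")
        within = (slopes.abs() <= 3 * ses).to_numpy()
        # individual 3-sigma misses have probability ~0.3%
        assert within.mean() > 0.95

    def test_duplicated_data_scales_standard_errors(self, truth):
        survey = generate_cognitive_survey(1200, truth, seed=6)
        m1 = fit_cognitive_probit(survey)
        m2 = fit_cognitive_probit(
            pd.concat([survey, survey], ignore_index=True), corr_subsample=2400
        )
        np.testing.assert_allclose(
            m1.coefficients.to_numpy(), m2.coefficients.to_numpy(), atol=1e-5
        )
        ratio = m1.standard_errors.to_numpy() / m2.standard_errors.to_numpy()
        np.testing.assert_allclose(ratio, np.sqrt(2.0), rtol=1e-3)

    def test_degenerate_outcome_raises_named_error(self, truth):
        survey = generate_cognitive_survey(500, truth, seed=7)
        survey[PROBIT_OUTCOMES[2]] = 0
        with pytest.raises(FitFailureError, match=PROBIT_OUTCOMES[2]):
            fit_cognitive_probit(survey)

    def test_correlation_estimate_recovers_exchangeable_truth(self, truth):
        survey = generate_cognitive_survey(8000, truth, seed=8)
        model = fit_cognitive_probit(survey)
        off = model.correlation[~np.eye(10, dtype=bool)]
        assert abs(off.mean() - 0.3) < 0.08


class TestCalibration:
    def test_target_zero_gives_theta_one(self):
        rng = np.random.default_rng(0)
        p = rng.random(500) * 0.9
        thr = calibrate_thresholds(p, p * 0.5, target_dementia=0.0, target_mci=0.0)
        assert thr.theta_dementia == 1.0
        assert (classify_cognition(p, p * 0.5, thr) == 0).all()

    def test_order_statistic_oracle_uniform(self):
        rng = np.random.default_rng(1)
        p_joint = rng.random(1000)
        p_fail = np.maximum(p_joint, rng.random(1000))
        thr = calibrate_thresholds(p_fail, p_joint, target_dementia=0.10, target_mci=0.15)
        kth_largest = np.sort(p_joint)[::-1][99]
        assert thr.theta_dementia == kth_largest
        assert thr.achieved_dementia == 0.1
        labels = classify_cognition(p_fail, p_joint, thr)
        assert (labels == 2).mean() == thr.achieved_dementia
        assert (labels == 1).mean() == thr.achieved_mci

    def test_boundary_target_full_prevalence(self):
        p = np.linspace(0.01, 0.99, 100)
        thr = calibrate_thresholds(p, p, target_dementia=1.0, target_mci=0.0)
        assert thr.achieved_dementia == 1.0

    def test_unreachable_target_errors(self):
        p = np.full(100, 0.5)  # total tie: only shares 0 and 1 attainable
        with pytest.raises(CalibrationError):
            calibrate_thresholds(p, p, target_dementia=0.37, target_mci=0.0)

    def test_prevalence_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        p = rng.random(400)
        shares = [np.mean(p >= t) for t in np.linspace(0, 1, 23)]
        assert all(a >= b for a, b in zip(shares, shares[1:]))


class TestClassification:
    def test_zero_probabilities_normal(self):
        thr = CognitionThresholds(theta_dementia=0.5, theta_mci=0.3)
        assert classify_cognition(0.0, 0.0, thr)[0] == 0

    def test_joint_probability_one_is_dementia(self):
        thr = CognitionThresholds(theta_dementia=0.99, theta_mci=0.3)
        assert classify_cognition(1.0, 1.0, thr)[0] == 2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        p_fail = rng.random(300)
        p_joint = p_fail * rng.random(300)
        thr = calibrate_thresholds(p_fail, p_joint, 0.2, 0.2)
        labels = classify_cognition(p_fail, p_joint, thr)
        sq = lambda x: np.asarray(x) ** 2  # strictly monotone on [0,1]
        thr_sq = CognitionThresholds(
            theta_dementia=float(sq(thr.theta_dementia)),
            theta_mci=float(sq(thr.theta_mci)),
        )
        labels_sq = classify_cognition(sq(p_fail), sq(p_joint), thr_sq)
        np.testing.assert_array_equal(labels, labels_sq)

    def test_json_round_trip(self, truth):
        survey = generate_cognitive_survey(800, truth, seed=10)
        model = fit_cognitive_probit(survey)
        back = ProbitModel.from_json(model.to_json())
        np.testing.assert_allclose(
            back.coefficients.to_numpy(), model.coefficients.to_numpy()
        )
        np.testing.assert_allclose(back.correlation, model.correlation)
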