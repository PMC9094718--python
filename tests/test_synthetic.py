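"""Generator behaviour: configured rates, degenerate limits, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import caresim.synthetic as syn
from caresim import (
    CalibrationTarget,
    ConfigurationError,
    GeneratorConfig,
    generate_baseline_population,
    generate_cognitive_survey,
    generate_frailty_survey,
    generate_target_prevalence,
    generate_transition_parameters,
    generate_utilization_claims,
)
from caresim.core import CONDITIONS, N_AGE_BANDS, age_band_midpoint


def neg_inf_logits():
    return {c: (-1e9, 0.0, 0.0, 0.0, 0.0) for c in CONDITIONS}


class TestGeneratorConfig:
    def test_invalid_education_shares_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(
                population_size=10,
                education_shares={"female": (0.5, 0.2, 0.2), "male": (0.4, 0.4, 0.2)},
            )

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(population_size=0)

    def test_age_range_must_start_at_60(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(population_size=10, age_range=(55, 80))


class TestBaselinePopulation:
    def test_degenerate_logits_give_zero_conditions(self):
        cfg = GeneratorConfig(
            population_size=500, condition_baseline_logits=neg_inf_logits(), seed=3
        )
        pop = generate_baseline_population(cfg)
        assert sum(pop[c].sum() for c in CONDITIONS) == 0
        assert pop["alive"].all()

    def test_point_mass_education(self):
        cfg = GeneratorConfig(
            population_size=500,
            education_shares={"female": (1.0, 0.0, 0.0), "male": (1.0, 0.0, 0.0)},
            seed=3,
        )
        pop = generate_baseline_population(cfg)
        assert (pop["education"] == 0).all()

    def test_diabetes_prevalence_matches_logistic_curve(self):
        # empirical prevalence by 5-year band vs the analytic logistic curve
        cfg = GeneratorConfig(population_size=50_000, seed=11)
        pop = generate_baseline_population(cfg)
        p = syn.condition_probability(
            cfg, "diabetes", pop["age"], pop["female"], pop["education"]
        )
        band = (pop["age"] // 5 * 5).astype(int)
        grouped = pd.DataFrame({"band": band, "y": pop["diabetes"], "p": p}).groupby("band")
        for _, g in grouped:
            n = len(g)
            if n < 200:
                continue
            expected = g["p"].mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(g["y"].mean() - expected) < 3 * se + 1e-12

    def test_seed_reproducibility(self):
        cfg = GeneratorConfig(population_size=300, seed=42)
        a = generate_baseline_population(cfg)
        b = generate_baseline_population(cfg)
        pd.testing.assert_frame_equal(a, b)
        c = generate_baseline_population(GeneratorConfig(population_size=300, seed=43))
        assert not a["age"].equals(c["age"])


class TestTransitionParameters:
    def test_zero_hazard_config_gives_zero_probabilities(self):
        cfg = GeneratorConfig(
            population_size=10,
            mortality_gompertz={"female": (-1e9, 0.0), "male": (-1e9, 0.0)},
            incidence_gompertz={c: (-1e9, 0.0) for c in CONDITIONS},
        )
        params = generate_transition_parameters(cfg)
        assert params.mortality.max() == 0.0
        assert params.incidence.max() == 0.0

    def test_probability_bounds_and_age_monotonicity(self):
        params = generate_transition_parameters(GeneratorConfig(population_size=10))
        for table in (params.incidence, params.mortality):
            assert table.min() >= 0.0 and table.max() <= 1.0
        # Gompertz hazards are monotone in age band
        assert (np.diff(params.mortality, axis=0) >= 0).all()
        assert (np.diff(params.incidence, axis=0) >= -1e-15).all()

    def test_education_gradient_in_mortality(self):
        params = generate_transition_parameters(GeneratorConfig(population_size=10))
        assert (params.mortality[:, :, 0] > params.mortality[:, :, 2]).all()

    def test_gompertz_formula_direct_evaluation(self):
        a, b = -10.0, 0.09
        cfg = GeneratorConfig(
            population_size=10,
            mortality_gompertz={"female": (a, b), "male": (a, b)},
            mortality_education_hr=(1.0, 1.0, 1.0),
        )
        params = generate_transition_parameters(cfg)
        mid = age_band_midpoint(np.arange(N_AGE_BANDS))
        expected = 1.0 - np.exp(-np.exp(a + b * mid) * 0.5)
        np.testing.assert_allclose(params.mortality[:, 0, 0], expected, rtol=1e-12)

    def test_round_trip_through_long_frame(self):
        params = generate_transition_parameters(GeneratorConfig(population_size=10))
        frame = params.to_frame()
        from caresim import TransitionParameters

        back = TransitionParameters.from_frame(frame, entry_schedule=params.entry_schedule)
        np.testing.assert_allclose(back.incidence, params.incidence)
        np.testing.assert_allclose(back.mortality, params.mortality)
        np.testing.assert_allclose(
            back.condition_mortality_loghr, params.condition_mortality_loghr
        )


class TestCognitiveSurvey:
    def test_symmetric_probit_rates(self, truth):
        # zero coefficients + identity correlation: every outcome has rate 1/2
        zero = truth.probit_coefficients * 0.0
        t = syn.TruthParameters(
            probit_coefficients=zero,
            probit_correlation=np.eye(len(syn.PROBIT_OUTCOMES)),
            frailty_logit_coefficients=truth.frailty_logit_coefficients,
            cost_coefficients=truth.cost_coefficients,
        )
        survey = generate_cognitive_survey(4000, t, seed=1)
        for name in syn.PROBIT_OUTCOMES:
            rate = survey[name].mean()
            assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / len(survey))

    def test_correlation_raises_pairwise_agreement(self, truth):
        zero = truth.probit_coefficients * 0.0
        k = len(syn.PROBIT_OUTCOMES)
        R = np.full((k, k), 0.9)
        np.fill_diagonal(R, 1.0)
        t_corr = syn.TruthParameters(
            probit_coefficients=zero,
            probit_correlation=R,
            frailty_logit_coefficients=truth.frailty_logit_coefficients,
            cost_coefficients=truth.cost_coefficients,
        )
        t_ind = syn.TruthParameters(
            probit_coefficients=zero,
            probit_correlation=np.eye(k),
            frailty_logit_coefficients=truth.frailty_logit_coefficients,
            cost_coefficients=truth.cost_coefficients,
        )
        s_corr = generate_cognitive_survey(4000, t_corr, seed=2)
        s_ind = generate_cognitive_survey(4000, t_ind, seed=2)
        a, b = syn.PROBIT_OUTCOMES[:2]
        agree_corr = (s_corr[a] == s_corr[b]).mean()
        agree_ind = (s_ind[a] == s_ind[b]).mean()
        assert agree_corr > agree_ind + 0.1

    def test_non_pd_correlation_rejected(self, truth):
        k = len(syn.PROBIT_OUTCOMES)
        R = np.full((k, k), 1.0)  # rank one, not PD -> config error at construction
        with pytest.raises(Exception):
            syn.TruthParameters(
                probit_coefficients=truth.probit_coefficients,
                probit_correlation=R,
                frailty_logit_coefficients=truth.frailty_logit_coefficients,
                cost_coefficients=truth.cost_coefficients,
            )


class TestFrailtySurvey:
    def test_default_fixture_size_and_age_support(self, truth):
        survey = generate_frailty_survey(1952, truth, seed=1)
        assert len(survey) == 1952
        assert (survey["age"] >= 65).all()

    def test_degenerate_intercept_gives_zero_frail(self, truth):
        coef = truth.frailty_logit_coefficients * 0.0
        coef["const"] = -1e9
        t = syn.TruthParameters(
            probit_coefficients=truth.probit_coefficients,
            probit_correlation=truth.probit_correlation,
            frailty_logit_coefficients=coef,
            cost_coefficients=truth.cost_coefficients,
        )
        survey = generate_frailty_survey(1000, t, seed=1)
        assert survey["frail"].sum() == 0


class TestUtilizationClaims:
    def test_intercept_only_truth(self, truth):
        coef = truth.cost_coefficients * 0.0
        coef["const"] = 123.0
        t = syn.TruthParameters(
            probit_coefficients=truth.probit_coefficients,
            probit_correlation=truth.probit_correlation,
            frailty_logit_coefficients=truth.frailty_logit_coefficients,
            cost_coefficients=coef,
            cost_noise_sd={"inpatient": 0.0, "outpatient_rx": 0.0},
        )
        claims = generate_utilization_claims(500, t, seed=1)
        assert (claims["inpatient"] == 123.0).all()
        assert (claims["outpatient_rx"] == 123.0).all()

    def test_use_increases_with_comorbidity(self, truth):
        base = pd.DataFrame(
            {"age": [75.0, 75.0], "female": [1, 1], "education": [1, 1]}
        )
        for c in CONDITIONS:
            base[c] = [0, 0]
        loaded = base.copy()
        for c in CONDITIONS[:5]:
            loaded[c] = [1, 1]
        mu0 = syn.expected_monthly_use(truth, base)
        mu5 = syn.expected_monthly_use(truth, loaded)
        assert (mu5.to_numpy() > mu0.to_numpy()).all()

    def test_non_negative(self, truth):
        claims = generate_utilization_claims(2000, truth, seed=9)
        assert (claims[["inpatient", "outpatient_rx"]] >= 0).all().all()


class TestCalibrationTarget:
    def test_constant_zero_curve_valid(self):
        target = generate_target_prevalence(
            {"dementia": {"female": (-1e9, 0.0), "male": (-1e9, 0.0)}}
        )
        assert (target.frame["prevalence"] == 0.0).all()

    def test_logistic_curve_formula(self):
        c0, c1 = -2.0, 0.1
        target = generate_target_prevalence(
            {"dementia": {"female": (c0, c1), "male": (c0, c1)}}
        )
        mid = age_band_midpoint(np.arange(N_AGE_BANDS))
        expected = expit(c0 + c1 * (mid - 75.0))
        got = (
            target.frame[target.frame["sex"] == "female"]
            .set_index("age_band")["prevalence"]
            .to_numpy()
        )
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_csv_round_trip(self, tmp_path):
        target = generate_target_prevalence()
        path = tmp_path / "targets.csv"
        target.to_csv(path)
        back = CalibrationTarget.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, target.frame)

    def test_out_of_range_prevalence_rejected(self):
        frame = pd.DataFrame(
            {"sex": ["female"], "age_band": ["60-64"], "condition": ["dementia"],
             "prevalence": [1.2]}
        )
        with pytest.raises(Exception):
            CalibrationTarget(frame)

    def test_overall_weighting(self):
        # overall target with a uniform curve equals the curve value
        target = generate_target_prevalence(
            {"dementia": {"female": (0.0, 0.0), "male": (0.0, 0.0)}}
        )
        pop = generate_baseline_population(GeneratorConfig(population_size=500, seed=1))
        assert abs(target.overall(pop, "dementia") - 0.5) < 1e-12
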