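"""Transition-engine dynamics: null cases, closed forms, invariants."""

import numpy as np
import pandas as pd
import pytest

from caresim import (
    DataError,
    MissingStratumError,
    PopulationState,
    TransitionParameters,
    half_year_from_interval,
    inject_entry_cohort,
    interval_from_half_year,
    simulate,
    step_half_year,
)
from caresim.core import CONDITIONS, N_AGE_BANDS
from caresim.engine import _FUNCTIONAL_KEYS

from conftest import make_population


def flat_params(q=0.0, incidence=0.0, entry_schedule=None, loghr=None, functional=0.0):
    return TransitionParameters(
        incidence=np.full((N_AGE_BANDS, 2, 3, len(CONDITIONS)), incidence),
        mortality=np.full((N_AGE_BANDS, 2, 3), q),
        condition_mortality_loghr=loghr if loghr is not None else np.zeros(len(CONDITIONS)),
        functional={k: np.full(N_AGE_BANDS, functional) for k in _FUNCTIONAL_KEYS},
        entry_schedule=entry_schedule,
    )


def schedule(year0=2016, years=30, count=0, shares=(1 / 3, 1 / 3, 1 / 3), survival=1.0):
    ys = np.arange(year0, year0 + years + 1)
    return pd.DataFrame(
        {
            "year": ys,
            "count": count,
            "share_less_than_high_school": shares[0],
            "share_high_school": shares[1],
            "share_college_or_higher": shares[2],
            "share_female": 0.5,
            "pre_entry_survival": survival,
        }
    )


class TestStepHalfYear:
    def test_null_dynamics_identity(self, population):
        state = PopulationState(population, 2016.0)
        out = step_half_year(state, flat_params(), np.random.default_rng(0))
        assert out.time == 2016.5
        expected = population.copy()
        expected["age"] += 0.5
        pd.testing.assert_frame_equal(out.frame, expected)

    def test_certain_mortality_absorbing(self, population):
        state = PopulationState(population, 2016.0)
        out = step_half_year(state, flat_params(q=1.0), np.random.default_rng(0))
        assert not out.frame["alive"].any()
        # dead are frozen: ages unchanged
        np.testing.assert_allclose(out.frame["age"], population["age"])

    def test_binomial_survival_closed_form(self):
        n, q = 50_000, 0.01
        pop = make_population(n)
        state = PopulationState(pop, 2016.0)
        rng = np.random.default_rng(5)
        params = flat_params(q=q)
        for _ in range(2):
            state = step_half_year(state, params, rng)
        expected = n * (1 - q) ** 2
        se = np.sqrt(n * (1 - q) ** 2 * (1 - (1 - q) ** 2))
        assert abs(state.n_alive - expected) < 3 * se

    def test_conditions_never_revert(self, population):
        state = PopulationState(population, 2016.0)
        params = flat_params(q=0.05, incidence=0.1)
        rng = np.random.default_rng(2)
        prev = state.frame[list(CONDITIONS)].to_numpy().copy()
        for _ in range(8):
            state = step_half_year(state, params, rng)
            cur = state.frame[list(CONDITIONS)].to_numpy()
            assert (cur >= prev).all()
            prev = cur.copy()

    def test_missing_stratum_named(self, population):
        params = flat_params(q=0.01)
        params.mortality[3, 1, 2] = np.nan
        state = PopulationState(population, 2016.0)
        with pytest.raises(MissingStratumError) as err:
            simulate(state, params, 3, np.random.default_rng(0), inject_entrants=False)
        msg = str(err.value)
        assert "75-79" in msg and "female" in msg and "college_or_higher" in msg


class TestEntryCohort:
    def test_zero_count_no_change(self, population):
        state = PopulationState(population, 2017.0)
        params = flat_params(entry_schedule=schedule(count=0))
        out = inject_entry_cohort(state, params, np.random.default_rng(0))
        pd.testing.assert_frame_equal(out.frame, state.frame)

    def test_point_mass_education_share(self, population):
        state = PopulationState(population, 2017.0)
        params = flat_params(entry_schedule=schedule(count=200, shares=(0.0, 0.0, 1.0)))
        out = inject_entry_cohort(state, params, np.random.default_rng(0))
        entrants = out.frame.iloc[len(population):]
        assert len(entrants) == 200
        assert (entrants["education"] == 2).all()
        assert entrants["age"].between(60, 62).all()
        assert out.frame["id"].is_unique

    def test_binomial_thinning(self, population):
        s = 0.9
        state = PopulationState(population, 2017.0)
        params = flat_params(entry_schedule=schedule(count=10_000, survival=s))
        out = inject_entry_cohort(state, params, np.random.default_rng(3))
        realized = len(out.frame) - len(population)
        se = np.sqrt(10_000 * s * (1 - s))
        assert abs(realized - 10_000 * s) < 3 * se

    def test_year_outside_schedule_errors(self, population):
        state = PopulationState(population, 2099.0)
        params = flat_params(entry_schedule=schedule())
        with pytest.raises(DataError):
            inject_entry_cohort(state, params, np.random.default_rng(0))


class TestSimulate:
    def test_horizon_zero_returns_baseline_only(self, population):
        state = PopulationState(population, 2016.0)
        traj = simulate(state, flat_params(), 0, np.random.default_rng(0))
        assert len(traj.snapshots) == 1
        pd.testing.assert_frame_equal(traj.snapshots[0].frame, population)

    def test_conservation_under_null_mortality(self, population):
        state = PopulationState(population, 2016.0)
        params = flat_params(entry_schedule=schedule(count=50))
        traj = simulate(state, params, 27, np.random.default_rng(1))
        cumulative = 0
        expected_years = list(range(2016, 2044, 3))
        assert traj.years == expected_years
        for snap in traj.snapshots:
            entered = sum(v for y, v in traj.entrants.items() if y <= snap.year)
            assert len(snap.frame) == len(population) + entered
            assert snap.n_alive == len(snap.frame)  # zero mortality

    def test_conservation_with_mortality(self, population):
        state = PopulationState(population, 2016.0)
        params = flat_params(q=0.03, entry_schedule=schedule(count=30))
        traj = simulate(state, params, 12, np.random.default_rng(1))
        for snap in traj.snapshots:
            entered = sum(v for y, v in traj.entrants.items() if y <= snap.year)
            alive = snap.n_alive
            dead = (~snap.frame["alive"]).sum()
            assert alive + dead == len(population) + entered

    def test_determinism_under_fixed_seed(self):
        pop = make_population(1000)
        params = flat_params(q=0.02, incidence=0.03, entry_schedule=schedule(count=20))
        t1 = simulate(PopulationState(pop.copy(), 2016.0), params, 9, np.random.default_rng(42))
        t2 = simulate(PopulationState(pop.copy(), 2016.0), params, 9, np.random.default_rng(42))
        for a, b in zip(t1.snapshots, t2.snapshots):
            pd.testing.assert_frame_equal(a.frame, b.frame)
        pd.testing.assert_frame_equal(t1.mortality_experience, t2.mortality_experience)

    def test_mortality_dominance_common_random_numbers(self):
        # raising one mortality cell never increases the later alive count
        pop = make_population(2000)
        base = flat_params(q=0.02, incidence=0.03, entry_schedule=schedule(count=25))
        raised = flat_params(q=0.02, incidence=0.03, entry_schedule=schedule(count=25))
        raised.mortality[2, 1, 1] = 0.5
        t_base = simulate(PopulationState(pop.copy(), 2016.0), base, 12, np.random.default_rng(7))
        t_raised = simulate(
            PopulationState(pop.copy(), 2016.0), raised, 12, np.random.default_rng(7)
        )
        for a, b in zip(t_base.snapshots, t_raised.snapshots):
            assert b.n_alive <= a.n_alive

    def test_mortality_experience_accounting(self, population):
        q = 0.05
        state = PopulationState(population, 2016.0)
        traj = simulate(state, flat_params(q=q), 3, np.random.default_rng(0),
                        inject_entrants=False)
        exp = traj.mortality_experience
        total_deaths = exp["deaths"].sum()
        assert total_deaths == (~traj.snapshots[-1].frame["alive"]).sum()
        # each alive person-step contributes half a year, minus a quarter at death
        assert 0 < exp["exposure"].sum() <= 0.5 * 6 * len(population)


class TestConversions:
    def test_half_year_three_year_round_trip(self):
        p3 = np.array([0.0, 0.05, 0.3, 0.9, 1.0])
        p_half = half_year_from_interval(p3, years=3)
        np.testing.assert_allclose(interval_from_half_year(p_half, years=3), p3, atol=1e-12)
        np.testing.assert_allclose(p_half, 1 - (1 - p3) ** (1 / 6))
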