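"""Cohort engine: transition structure, conservation, oracles."""

import numpy as np
import pytest

from sunbedban import build_cycle_transitions, microsimulate, run_cohort
from sunbedban.markov import (
    DEATH_MEL,
    DEATH_OTHER,
    NO_MEL,
    N_STATES,
    POST_THICK,
    POST_THIN,
    THICK_TUNNEL_FIRST,
    THIN,
    ModelError,
    transition_matrices,
)
from sunbedban.population import life_expectancy
from sunbedban.risk import arm_incidence_curve, other_cause_curve

from conftest import build_tables


def hand_built_matrix(q, i_mel, p_thick, year1, dec, post10, thin_excess):
    """Independent 16-state transition matrix written out entry by entry."""
    T = np.zeros((N_STATES, N_STATES))
    T[NO_MEL, DEATH_OTHER] = q
    T[NO_MEL, THIN] = (1 - q) * i_mel * (1 - p_thick)
    T[NO_MEL, THICK_TUNNEL_FIRST] = (1 - q) * i_mel * p_thick
    T[NO_MEL, NO_MEL] = (1 - q) * (1 - i_mel)
    for s in (THIN, POST_THIN):
        e = min(thin_excess, 1 - q)
        T[s, DEATH_OTHER] = q
        T[s, DEATH_MEL] = e
        T[s, POST_THIN] = 1 - q - e
    for year in range(1, 11):
        s = THICK_TUNNEL_FIRST + year - 1
        excess = min(max(year1 - (year - 1) * dec, 0.0), 1 - q)
        dest = s + 1 if year < 10 else POST_THICK
        T[s, DEATH_OTHER] = q
        T[s, DEATH_MEL] = excess
        T[s, dest] = 1 - q - excess
    e10 = min(post10, 1 - q)
    T[POST_THICK, DEATH_OTHER] = q
    T[POST_THICK, DEATH_MEL] = e10
    T[POST_THICK, POST_THICK] = 1 - q - e10
    T[DEATH_MEL, DEATH_MEL] = 1.0
    T[DEATH_OTHER, DEATH_OTHER] = 1.0
    return T


class TestTransitionStructure:
    def test_matches_hand_built_matrix(self, params, tables):
        age = 47
        T = build_cycle_transitions(age, "female", "status_quo", tables, params)
        idx = tables.age_index(age)
        expected = hand_built_matrix(
            other_cause_curve("female", tables)[idx],
            arm_incidence_curve("female", "melanoma", "status_quo", tables, params)[idx],
            params.p_thick,
            params.mort_thick_year1,
            params.mort_annual_decrement,
            params.mort_post10_excess,
            params.mort_thin_excess,
        )
        np.testing.assert_allclose(T, expected, atol=1e-15)

    def test_rows_sum_to_one(self, params, tables):
        T = transition_matrices("male", "ban", tables, params)
        np.testing.assert_allclose(T.sum(axis=2), 1.0, atol=1e-12)

    def test_death_states_absorbing(self, params, tables):
        T = build_cycle_transitions(30, "female", "ban", tables, params)
        assert T[DEATH_MEL, DEATH_MEL] == 1.0
        assert T[DEATH_OTHER, DEATH_OTHER] == 1.0

    def test_tunnel_survivors_advance_one_slot(self, params, tables):
        T = build_cycle_transitions(60, "female", "status_quo", tables, params)
        s9 = THICK_TUNNEL_FIRST + 8  # tunnel year 9
        survivors = 1.0 - T[s9, DEATH_MEL] - T[s9, DEATH_OTHER]
        assert T[s9, s9 + 1] == pytest.approx(survivors)
        assert np.all(np.delete(T[s9], [s9 + 1, DEATH_MEL, DEATH_OTHER]) == 0)

    def test_excess_capped_by_surviving_probability(self, params):
        """Other-cause death takes precedence: a melanoma excess larger than
        the surviving mass is capped rather than driving the residual
        negative."""
        t = build_tables(params, mortality=0.999, melanoma=1e-4)
        huge = params.model_copy(update={"mort_thin_excess": 0.5})
        T = transition_matrices("female", "status_quo", t, huge)
        np.testing.assert_allclose(T.sum(axis=2), 1.0, atol=1e-12)
        assert T[0, THIN, DEATH_MEL] == pytest.approx(0.001)
        assert T[0, THIN, POST_THIN] == pytest.approx(0.0, abs=1e-12)


class TestRunCohort:
    def test_identity_dynamics(self, params):
        t = build_tables(params)  # everything zero
        trace = run_cohort("female", "status_quo", t, params)
        assert trace.occupancy[-1, NO_MEL] == 1.0
        assert trace.thin_incidence.sum() == 0.0

    def test_extinction_under_certain_death(self, params):
        t = build_tables(params, mortality=1.0)
        trace = run_cohort("female", "status_quo", t, params)
        assert trace.occupancy[1, DEATH_OTHER] == 1.0
        assert trace.alive_mass[1:].sum() == 0.0
        assert trace.kc_incidence[1:].sum() == 0.0

    def test_mass_conserved_every_cycle(self, params, tables):
        for arm in ("status_quo", "ban"):
            trace = run_cohort("male", arm, tables, params)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.diff(trace.alive_mass) <= 1e-12)
            deaths = trace.occupancy[:, DEATH_MEL] + trace.occupancy[:, DEATH_OTHER]
            assert np.all(np.diff(deaths) >= -1e-12)

    def test_matches_matrix_power_oracle(self, params, tables):
        """Occupancy and cumulative incident melanoma mass agree with an
        explicit step-by-step matrix-product computation."""
        trace = run_cohort("female", "ban", tables, params)
        occ = np.zeros(N_STATES)
        occ[NO_MEL] = 1.0
        cum_inc = 0.0
        for t in range(params.n_cycles):
            T = build_cycle_transitions(18 + t, "female", "ban", tables, params)
            cum_inc += occ @ T[:, THIN] + occ @ T[:, THICK_TUNNEL_FIRST]
            occ = occ @ T
        np.testing.assert_allclose(trace.occupancy[-1], occ, atol=1e-10)
        assert cum_inc == pytest.approx(
            trace.thin_incidence.sum() + trace.thick_incidence.sum(), abs=1e-10
        )

    def test_life_years_match_life_table(self, params, tables):
        """With melanoma switched off, cohort person-years equal the life
        table's survival-curve life expectancy."""
        off = params.model_copy(update={"rr_melanoma": 1.0, "rr_kc": 1.0})
        t = build_tables(params, mortality=tables.all_cause_mortality["female"])
        trace = run_cohort("female", "status_quo", t, off)
        q = tables.all_cause_mortality["female"][: params.n_cycles]
        expected = 1.0 + np.cumprod(1.0 - q)[:-1].sum() + np.prod(1.0 - q)
        assert trace.alive_mass.sum() == pytest.approx(expected, abs=1e-9)
        # and against the packaged life-expectancy helper on the same span
        assert trace.alive_mass.sum() == pytest.approx(
            life_expectancy(np.append(q, 1.0)), abs=1e-9
        )


class TestMicrosimulation:
    def test_deterministic_under_seed(self, params, tables):
        small = params.model_copy(update={"n_cycles": 20})
        a = microsimulate("female", "ban", tables, small, 500, np.random.default_rng(3))
        b = microsimulate("female", "ban", tables, small, 500, np.random.default_rng(3))
        assert a == b

    def test_single_riskless_individual(self, params):
        t = build_tables(params, norm=0.9)
        r = microsimulate("female", "status_quo", t, params, 1, np.random.default_rng(0))
        disc = (1 + params.discount_rate) ** -np.arange(params.n_cycles + 1)
        u = 0.9 * disc
        expected = float(np.sum(0.5 * (u[:-1] + u[1:])))
        assert r.mean_cost == 0.0
        assert r.mean_qalys == pytest.approx(expected, rel=1e-12)

    def test_invalid_population_size(self, params, tables):
        with pytest.raises(ValueError):
            microsimulate("female", "ban", tables, params, 0, np.random.default_rng(0))
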