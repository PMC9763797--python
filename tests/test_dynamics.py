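"""Per-meal engine: preference draws, norm mixing, the hand-checked oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dietnorms.dynamics import (
    AgentStates,
    Clock,
    StepContext,
    group_norm,
    household_choice,
    init_states,
    internal_preference,
    mixed_preference,
    step_meal,
)
from dietnorms.population import PopulationArrays


def _clipped_normal_moments(mu, sigma, lo=0.0, hi=100.0):
    """Mean and SD of clip(N(mu, sigma), lo, hi), by censored-normal algebra."""
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    phi_a, phi_b = stats.norm.pdf(a), stats.norm.pdf(b)
    Phi_a, Phi_b = stats.norm.cdf(a), stats.norm.cdf(b)
    mean = lo * Phi_a + hi * (1 - Phi_b) + mu * (Phi_b - Phi_a) - sigma * (phi_b - phi_a)
    e2 = (
        lo**2 * Phi_a
        + hi**2 * (1 - Phi_b)
        + (mu**2 + sigma**2) * (Phi_b - Phi_a)
        - sigma * ((hi + mu) * phi_b - (lo + mu) * phi_a)
    )
    return mean, np.sqrt(e2 - mean**2)


class TestInternalPreference:
    def test_zero_sd_returns_running_mean(self, rng):
        assert internal_preference(42.5, 0.0, rng) == 42.5

    def test_centred_on_running_mean(self, rng):
        draws = np.clip(rng.normal(40.0, 13.5, size=100_000), 0, 100)
        mc_se = 13.5 / np.sqrt(100_000)
        assert abs(draws.mean() - 40.0) < 3 * mc_se
        sample = np.array([internal_preference(40.0, 13.5, rng) for _ in range(2000)])
        assert abs(sample.mean() - 40.0) < 4 * 13.5 / np.sqrt(2000)

    def test_sd_matches_clipped_normal_oracle(self, rng):
        mu, sigma = 10.0, 20.0  # heavy clipping at the lower bound
        oracle_mean, oracle_sd = _clipped_normal_moments(mu, sigma)
        draws = np.array([internal_preference(mu, sigma, rng) for _ in range(50_000)])
        assert abs(draws.mean() - oracle_mean) < 0.3
        assert abs(draws.std() - oracle_sd) < 0.3


class TestHouseholdAndGroupNorms:
    def test_household_mean(self):
        assert household_choice([30.0, 50.0]) == 40.0

    def test_single_member_unchanged(self):
        assert household_choice([61.3]) == 61.3

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=8))
    def test_household_choice_bounded_by_extremes(self, prefs):
        c = household_choice(prefs)
        assert min(prefs) - 1e-9 <= c <= max(prefs) + 1e-9

    def test_group_norm_convention(self):
        mean, sd = group_norm([40.0, 60.0])
        assert mean == 50.0
        assert sd == pytest.approx(np.std([40.0, 60.0], ddof=1))

    def test_identical_preferences_zero_sd(self):
        assert group_norm([55.0, 55.0, 55.0]) == (55.0, 0.0)

    def test_single_coeater_zero_sd(self):
        assert group_norm([70.0])[1] == 0.0

    def test_matches_direct_recomputation(self, rng):
        prefs = rng.uniform(0, 100, size=17)
        mean, sd = group_norm(prefs)
        assert mean == pytest.approx(prefs.mean(), abs=1e-9)
        assert sd == pytest.approx(prefs.std(ddof=1), abs=1e-9)


class TestMixedPreference:
    def test_degenerate_weights_match_component(self, rng):
        # w=0 -> indistinguishable from the personal norm; w=1 -> the group norm
        n = 10_000
        for w, (mean, sd) in ((0.0, (30.0, 5.0)), (1.0, (60.0, 8.0))):
            draws = np.array(
                [mixed_preference((30.0, 5.0), (60.0, 8.0), w, rng) for _ in range(n)]
            )
            reference = np.clip(rng.normal(mean, sd, size=n), 0, 100)
            assert stats.ks_2samp(draws, reference).pvalue > 0.001

    def test_equal_weight_mixture_mean(self, rng):
        draws = np.array(
            [mixed_preference((30.0, 0.0), (50.0, 0.0), 0.5, rng) for _ in range(10_000)]
        )
        assert set(np.unique(draws)) == {30.0, 50.0}
        assert abs(draws.mean() - 40.0) < 3 * 10.0 / np.sqrt(10_000)

    def test_invalid_weight_rejected(self, rng):
        with pytest.raises(ValueError):
            mixed_preference((30, 5), (60, 8), 1.5, rng)


class TestAgentStates:
    def test_prefill_running_mean_exact(self):
        states = AgentStates.from_initial(np.array([38.1, 55.0]), history_length=45)
        np.testing.assert_allclose(states.running_mean, [38.1, 55.0])
        assert states.history.shape == (2, 45)

    def test_incremental_mean_tracks_direct_mean(self, rng):
        states = AgentStates.from_initial(rng.uniform(0, 100, 50), history_length=45)
        for _ in range(200):
            states.update(rng.uniform(0, 100, 50))
        np.testing.assert_allclose(states.running_mean, states.recompute_means(), atol=1e-9)

    def test_window_evicts_oldest(self):
        states = AgentStates.from_initial(np.array([0.0]), history_length=3)
        for v in (30.0, 60.0, 90.0):
            states.update(np.array([v]))
        assert states.running_mean[0] == pytest.approx(60.0)


class TestInitStates:
    def test_population_median_emulates_survey_distribution(self, rng):
        arrays = _toy_population(n=10_000)
        states, initial = init_states(arrays, (37.4, 18.7), rng=rng)
        assert abs(np.median(initial) - 38.0) < 1.0
        np.testing.assert_allclose(states.running_mean, initial)

    def test_zero_sd_all_identical(self, rng):
        arrays = _toy_population(n=5)
        states, initial = init_states(arrays, (40.0, 0.0), rng=rng)
        assert (initial == 40.0).all()


def _toy_population(n=3, roles=None, venues=None, sigma=0.0, w=0.0):
    roles = np.asarray(roles if roles is not None else [1] * n, dtype=np.int8)
    venues = np.asarray(venues if venues is not None else [-1] * n, dtype=np.int64)
    return PopulationArrays(
        role=roles,
        household_id=np.zeros(roles.size, dtype=np.int64),
        venue_id=venues,
        sigma_pref=np.full(roles.size, float(sigma)),
        w_group=np.full(roles.size, float(w)),
        n_households=1,
        venue_kind=np.array(["workplace-big", "school-primary"], dtype=object),
    )


class TestStepMeal:
    def test_weekend_lunch_all_within_household(self, rng):
        pop = _toy_population(roles=[0, 1, 2], venues=[0, -1, 1], sigma=5.0, w=0.5)
        states, _ = init_states(pop, (40.0, 10.0), rng=rng)
        clock = Clock(step=5 * 3 + 1)  # Saturday lunch
        ctx = StepContext(home_scores=np.sort(rng.uniform(0, 100, 50)))
        chosen, at_venue = step_meal(states, pop, clock, ctx, rng)
        assert not at_venue.any()
        assert len(set(chosen)) == 1  # one shared household meal

    def test_household_members_share_identical_recorded_meal(self, rng):
        pop = _toy_population(roles=[1, 1, 1], sigma=8.0)
        states, _ = init_states(pop, (40.0, 15.0), rng=rng)
        ctx = StepContext(home_scores=np.sort(rng.uniform(0, 100, 200)))
        chosen, _ = step_meal(states, pop, Clock(0), ctx, rng)
        assert len(set(chosen)) == 1

    def test_conservation_one_meal_per_agent(self, rng):
        pop = _toy_population(roles=[0, 1, 2], venues=[0, -1, 1], sigma=5.0, w=0.5)
        states, _ = init_states(pop, (40.0, 10.0), rng=rng)
        menus = {0: np.array([62.0, 70.0]), 1: np.array([61.0, 80.0])}
        ctx = StepContext(home_scores=np.sort(rng.uniform(0, 100, 50)), venue_menus=menus)
        chosen, at_venue = step_meal(states, pop, Clock(1), ctx, rng)  # Monday lunch
        assert chosen.shape == (3,)
        assert ((chosen >= 0) & (chosen <= 100)).all()
        assert at_venue.tolist() == [True, False, True]
        assert chosen[0] >= 62.0 and chosen[2] >= 61.0  # venue meals meet the menus

    def test_isolated_worker_eats_at_home(self, rng):
        pop = _toy_population(roles=[0, 1], venues=[0, -1], sigma=5.0)
        states, _ = init_states(pop, (40.0, 10.0), rng=rng)
        isolated = np.array([True, False])
        ctx = StepContext(
            home_scores=np.sort(rng.uniform(0, 100, 50)),
            venue_menus={0: np.array([65.0])},
            isolated=isolated,
        )
        chosen, at_venue = step_meal(states, pop, Clock(1), ctx, rng)
        assert not at_venue.any()
        assert chosen[0] == chosen[1]

    def test_hand_simulated_three_agent_oracle(self, rng):
        """Two steps of a 3-agent household, all noise off, checked by hand.

        Worker (mean 30), nonworking adult (50), child (70); H=3; home list
        {20,40,60,80}; workplace menu {65,75}; school menu {55,85}.
        """
        pop = _toy_population(roles=[0, 1, 2], venues=[0, -1, 1], sigma=0.0, w=0.0)
        states = AgentStates.from_initial(np.array([30.0, 50.0, 70.0]), history_length=3)
        home = np.array([20.0, 40.0, 60.0, 80.0])
        menus = {0: np.array([65.0, 75.0]), 1: np.array([55.0, 85.0])}

        # Monday breakfast: household mean (30+50+70)/3 = 50, equidistant
        # between 40 and 60 -> tie resolves to 60; everyone records 60.
        chosen0, at0 = step_meal(states, pop, Clock(0), StepContext(home_scores=home), rng)
        assert chosen0.tolist() == [60.0, 60.0, 60.0]
        assert not at0.any()
        np.testing.assert_allclose(states.running_mean, [40.0, 160 / 3, 200 / 3])

        # Monday lunch: worker pref 40 -> nearest of {65,75} = 65; child pref
        # 200/3 -> nearest of {55,85} = 55; adult home alone -> mean 160/3 -> 60.
        ctx = StepContext(home_scores=home, venue_menus=menus)
        chosen1, at1 = step_meal(states, pop, Clock(1), ctx, rng)
        assert chosen1.tolist() == [65.0, 60.0, 55.0]
        assert at1.tolist() == [True, False, True]
        np.testing.assert_allclose(states.running_mean, [155 / 3, 170 / 3, 185 / 3])

    def test_missing_menu_raises(self, rng):
        pop = _toy_population(roles=[0], venues=[0], sigma=1.0)
        states, _ = init_states(pop, (40.0, 5.0), rng=rng)
        ctx = StepContext(home_scores=np.array([50.0]))
        with pytest.raises(RuntimeError):
            step_meal(states, pop, Clock(1), ctx, rng)
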