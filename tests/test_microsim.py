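import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vte_sim.microsim import (
    cycle_uniforms,
    expectation_oracle,
    run_cohort,
    simulate_cohort,
    simulate_patient,
)
from vte_sim.params import ModelParams


def make_profile(p_vte_off=0.089, p_vte_on=0.0139, p_bleed_off=0.034, p_bleed_on=0.0668):
    return pd.Series(
        {
            "p_vte_5y_off": p_vte_off,
            "p_vte_5y_on": p_vte_on,
            "p_bleed_5y_off": p_bleed_off,
            "p_bleed_5y_on": p_bleed_on,
            "arr": p_vte_off - p_vte_on,
            "ari": p_bleed_on - p_bleed_off,
        }
    )


def replicate(profile, n):
    return pd.DataFrame([profile] * n).reset_index(drop=True)


ZERO_MORT = np.zeros(20)


def perfect_health_params():
    p = ModelParams()
    p.utilities.baseline = 1.0
    return p


class TestSinglePatientTrajectories:
    def test_event_free_life_accrues_full_qalys(self):
        profile = make_profile(0, 0, 0, 0)
        traj = simulate_patient(0, profile, False, ZERO_MORT, perfect_health_params(), seed=1)
        assert (traj.records["state"] == "event_free").all()
        assert traj.qalys == pytest.approx(5.0)
        assert traj.events == []

    def test_immediate_death_accrues_nothing(self):
        profile = make_profile(0, 0, 0, 0)
        mort = np.zeros(20)
        mort[0] = 1.0
        traj = simulate_patient(0, profile, False, mort, perfect_health_params(), seed=1)
        assert (traj.records["state"] == "dead").all()
        assert traj.qalys == 0.0  # no half-cycle credit

    def test_certain_nonmajor_bleeding_every_cycle(self):
        params = perfect_health_params()
        params.events.p_crnmb_given_bleed = 1.0
        profile = make_profile(0, 0, 1.0, 1.0)
        traj = simulate_patient(0, profile, False, ZERO_MORT, params, seed=1)
        assert (traj.records["state"] == "crnmb").all()
        assert len(traj.events) == 20
        expected = 5.0 - 20 * 0.25 * params.utilities.dis_crnmb
        assert traj.qalys == pytest.approx(expected)

    def test_exactly_one_state_per_cycle_until_death(self, small_base):
        profile = small_base.profiles.iloc[0]
        traj = simulate_patient(0, profile, True, small_base.mort_cycle[0], ModelParams(), seed=3)
        assert len(traj.records) == 20
        dead = traj.records["state"] == "dead"
        if dead.any():
            first = int(np.flatnonzero(dead)[0])
            assert dead.iloc[first:].all()
            assert (traj.records["utility"].iloc[first:] == 0).all()


class TestCohortRuns:
    def test_deterministic_under_fixed_seed(self, small_base):
        treated = np.ones(len(small_base.cohort), dtype=bool)
        kwargs = dict(
            cohort=small_base.cohort,
            profiles=small_base.profiles,
            treated=treated,
            mort_cycle=small_base.mort_cycle,
            params=small_base.params,
        )
        a = run_cohort(seed=5, **kwargs)
        b = run_cohort(seed=5, **kwargs)
        assert (a.qalys, a.recurrences, a.bleeds, a.deaths) == (
            b.qalys,
            b.recurrences,
            b.bleeds,
            b.deaths,
        )

    def test_results_invariant_to_cohort_ordering(self, small_base):
        perm = np.random.default_rng(0).permutation(len(small_base.cohort))
        treated = np.zeros(len(small_base.cohort), dtype=bool)
        a = run_cohort(
            small_base.cohort, small_base.profiles, treated, small_base.mort_cycle,
            small_base.params, seed=5,
        )
        b = run_cohort(
            small_base.cohort.iloc[perm].reset_index(drop=True),
            small_base.profiles.iloc[perm].reset_index(drop=True),
            treated[perm], small_base.mort_cycle[perm], small_base.params, seed=5,
        )
        assert a.qalys == pytest.approx(b.qalys)
        assert (a.recurrences, a.bleeds, a.deaths) == (b.recurrences, b.bleeds, b.deaths)

    def test_zero_risk_cohort(self):
        n = 50
        profiles = replicate(make_profile(0, 0, 0, 0), n)
        params = ModelParams()
        res = simulate_cohort(
            profiles, np.zeros(n, bool), np.tile(ZERO_MORT, (n, 1)), params,
            cycle_uniforms(1, np.arange(n)),
        )
        assert res.recurrences == res.bleeds == res.deaths == 0
        assert res.qalys == pytest.approx(5 * n * params.utilities.baseline)

    def test_assignment_mismatch_is_an_error(self, small_base):
        with pytest.raises(ValueError, match="assignment"):
            run_cohort(
                small_base.cohort, small_base.profiles, np.ones(3, bool),
                small_base.mort_cycle, small_base.params, seed=1,
            )

    def test_first_recurrence_count_matches_binomial_oracle(self):
        """Recurrence-only model: patients with ≥1 event follow Binomial(n, p5)."""
        n, p5 = 100_000, 0.10
        params = ModelParams()
        params.events.cf_pe = 0.0
        params.events.p_pts_after_dvt = 0.0
        params.events.p_cteph_after_pe = 0.0
        profiles = replicate(make_profile(p5, p5, 0.0, 0.0), n)
        _, (states, _, _) = simulate_cohort(
            profiles, np.zeros(n, bool), np.tile(ZERO_MORT, (n, 1)), params,
            cycle_uniforms(2, np.arange(n)), trace=True,
        )
        had_event = np.isin(states, ["recurrent_pe", "recurrent_dvt"]).any(axis=1).sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p5)
        assert lo <= had_event <= hi


class TestExpectationOracle:
    def test_zero_event_expectation(self):
        params = perfect_health_params()
        out = expectation_oracle(make_profile(0, 0, 0, 0), False, ZERO_MORT, params)
        assert out["qalys"] == pytest.approx(5.0)
        assert out["deaths"] == pytest.approx(0.0)

    def test_exponential_mortality_expectation(self):
        mort = np.full(20, 1 - (1 - 0.107) ** (1 / 20))
        out = expectation_oracle(make_profile(0, 0, 0, 0), False, mort, ModelParams())
        assert out["deaths"] == pytest.approx(0.107, abs=1e-12)

    @pytest.mark.parametrize("treated", [True, False])
    def test_microsim_means_converge_to_oracle(self, treated):
        n = 60_000
        params = ModelParams()
        profile = make_profile()
        mort = np.full(20, 0.0056425)
        res = simulate_cohort(
            replicate(profile, n), np.full(n, treated), np.tile(mort, (n, 1)), params,
            cycle_uniforms(7, np.arange(n)), keep_per_patient=True,
        )
        oracle = expectation_oracle(profile, treated, mort, params)
        se_q = res.per_patient_qalys.std() / np.sqrt(n)
        assert res.qalys / n == pytest.approx(oracle["qalys"], abs=3.5 * se_q)
        for key, value in [
            ("recurrences", res.recurrences),
            ("bleeds", res.bleeds),
            ("deaths", res.deaths),
        ]:
            expected = oracle[key] * n
            assert abs(value - expected) <= 3.5 * np.sqrt(expected)

    def test_treat_all_beats_treat_none_in_benefit_only_limit(self):
        """With no bleeding harm (hr_bleed=1) treatment can only add QALYs."""
        params = ModelParams()
        profile = make_profile(0.089, 0.0139, 0.034, 0.034)
        mort = np.full(20, 0.005)
        on = expectation_oracle(profile, True, mort, params)
        off = expectation_oracle(profile, False, mort, params)
        assert on["qalys"] >= off["qalys"]

    def test_qalys_monotone_in_disutilities_and_utilities(self):
        profile = make_profile()
        mort = np.full(20, 0.005)
        base = expectation_oracle(profile, True, mort, ModelParams())
        worse = ModelParams()
        worse.utilities.dis_pe = 0.4
        worse.utilities.dis_crnmb = 0.2
        assert expectation_oracle(profile, True, mort, worse)["qalys"] <= base["qalys"]
        better = ModelParams()
        better.utilities.pts = 0.85
        assert expectation_oracle(profile, True, mort, better)["qalys"] >= base["qalys"]

    def test_discontinuation_increases_recurrences(self):
        profile = make_profile()
        mort = np.full(20, 0.005)
        params = ModelParams()
        disc = ModelParams()
        disc.behavior.p_discontinue_cycle = 0.05
        assert (
            expectation_oracle(profile, True, mort, disc)["recurrences"]
            > expectation_oracle(profile, True, mort, params)["recurrences"]
        )


def test_invalid_probability_is_rejected(small_base):
    profiles = small_base.profiles.copy()
    profiles.loc[profiles.index[0], "p_vte_5y_on"] = 1.3
    with pytest.raises(ValueError):
        run_cohort(
            small_base.cohort, profiles,
            np.ones(len(profiles), bool), small_base.mort_cycle, small_base.params, seed=1,
        )
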