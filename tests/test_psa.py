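import numpy as np
import pandas as pd
import pytest

from vte_sim.params import ModelParams
from vte_sim.policies import RatioGrid
from vte_sim.psa import (
    ParamDistribution,
    SamplingSpec,
    ScenarioConfig,
    default_sampling_spec,
    one_way_sensitivity,
    optimal_ratio,
    run_psa,
    run_scenario,
    sample_params,
    scenario_params,
    sweep_ratios,
)


def fixed_spec():
    return SamplingSpec(
        distributions={
            name: ParamDistribution(kind="fixed")
            for name in default_sampling_spec().distributions
        }
    )


class TestSweep:
    def test_toy_proportions_by_enumeration(self, small_base):
        profiles = pd.DataFrame(
            {
                "p_vte_5y_off": [0.05, 0.08],
                "p_vte_5y_on": [0.03, 0.04],
                "p_bleed_5y_off": [0.02, 0.02],
                "p_bleed_5y_on": [0.03, 0.03],
                "arr": [0.02, 0.04],
                "ari": [0.01, 0.01],
            }
        )
        cohort = small_base.cohort.iloc[:2].reset_index(drop=True)
        sweep = sweep_ratios(
            cohort, profiles, RatioGrid((1.0, 3.0, 5.0)),
            small_base.mort_cycle[:2], small_base.params, seed=0, prune=False,
        )
        assert list(sweep["proportion_treated"]) == [1.0, 0.5, 0.0]

    def test_null_effect_makes_assignment_irrelevant(self, small_base):
        profiles = small_base.profiles.copy()
        profiles["p_vte_5y_on"] = profiles["p_vte_5y_off"]
        profiles["p_bleed_5y_on"] = profiles["p_bleed_5y_off"]
        profiles["arr"] = 0.0
        profiles["ari"] = 0.0
        sweep = sweep_ratios(
            small_base.cohort, profiles, RatioGrid((0.5, 1.0, 2.0)),
            small_base.mort_cycle, small_base.params, seed=3, prune=False,
        )
        assert sweep["qalys"].nunique() == 1
        assert sweep["recurrences"].nunique() == 1

    def test_event_tradeoff_across_ratios(self, base_case):
        """More weight on bleeding → fewer treated → more recurrences, fewer bleeds."""
        sweep = sweep_ratios(
            base_case.cohort, base_case.profiles, RatioGrid.base(step=1.0),
            base_case.mort_cycle, base_case.params, seed=11,
        )
        assert (np.diff(sweep["proportion_treated"]) <= 1e-12).all()
        assert sweep["recurrences"].iloc[-1] > sweep["recurrences"].iloc[0]
        assert sweep["bleeds"].iloc[-1] < sweep["bleeds"].iloc[0]


class TestOptimalRatio:
    def test_argmax(self):
        sweep = pd.DataFrame({"ratio": [0.5, 0.9, 2.0], "qalys": [39700, 39780, 39750]})
        assert optimal_ratio(sweep) == 0.9

    def test_tie_breaks_to_lowest_ratio(self):
        sweep = pd.DataFrame({"ratio": [0.9, 1.0, 1.5], "qalys": [100.0, 100.0, 90.0]})
        assert optimal_ratio(sweep) == 0.9

    def test_empty_sweep_is_an_error(self):
        with pytest.raises(ValueError):
            optimal_ratio(pd.DataFrame({"ratio": [], "qalys": []}))


class TestSampling:
    def test_fixed_distributions_return_base_values(self):
        base = ModelParams()
        drawn = sample_params(base, fixed_spec(), np.random.default_rng(0))
        assert drawn == base

    def test_sampled_values_stay_in_support(self):
        base = ModelParams()
        spec = default_sampling_spec()
        rng = np.random.default_rng(1)
        for _ in range(50):
            drawn = sample_params(base, spec, rng)
            assert 0 < drawn.events.cf_ich < 1
            assert 0 < drawn.utilities.baseline < 1
            assert drawn.effect.hr_vte > 0
            assert drawn.utilities.dis_pe > 0

    def test_unknown_parameter_is_rejected_with_names(self):
        spec = SamplingSpec(distributions={"events.nope": ParamDistribution(kind="fixed")})
        with pytest.raises(KeyError, match="events.cf_pe"):
            sample_params(ModelParams(), spec, np.random.default_rng(0))


class TestPSA:
    def test_reproducible_under_master_seed(self, small_base):
        kwargs = dict(
            cohort=small_base.cohort, surrogate=small_base.surrogate,
            base_params=small_base.params, grid=RatioGrid.base(step=2.0),
            reps=3, master_seed=5,
        )
        a, b = run_psa(**kwargs), run_psa(**kwargs)
        np.testing.assert_array_equal(a.per_rep_optimal, b.per_rep_optimal)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_degenerate_distributions_collapse_replications(self, small_base):
        """Zero parameter uncertainty ⇒ identical replications, zero CI width."""
        res = run_psa(
            small_base.cohort, small_base.surrogate, small_base.params,
            RatioGrid.base(step=2.0), reps=3, master_seed=5, sampling=fixed_spec(),
        )
        assert np.ptp(res.per_rep_optimal) == 0.0
        lo, hi = res.optimal_ratio_ci
        assert hi - lo == 0.0
        assert np.ptp(res.qalys, axis=0).max() == 0.0

    def test_summary_and_traces(self, small_base):
        res = run_psa(
            small_base.cohort, small_base.surrogate, small_base.params,
            RatioGrid.base(step=2.0), reps=4, master_seed=9,
        )
        assert res.reps == 4
        trace = res.convergence_trace()
        assert len(trace) == 4
        assert trace["running_mean_optimal"].iloc[-1] == pytest.approx(res.mean_optimal_ratio)
        lo, hi = res.optimal_ratio_ci
        assert res.grid.min() <= lo <= hi <= res.grid.max()
        summary = res.summary()
        assert summary["replications"] == 4
        assert "mean_soc_qalys" in summary

    def test_requires_at_least_two_replications(self, small_base):
        with pytest.raises(ValueError):
            run_psa(
                small_base.cohort, small_base.surrogate, small_base.params,
                RatioGrid.base(step=2.0), reps=1, master_seed=1,
            )


class TestOneWaySensitivity:
    def test_degenerate_bounds_give_zero_delta(self, small_base):
        rows = one_way_sensitivity(
            "utilities.pts", 0.75, 0.75, small_base.cohort, small_base.surrogate,
            small_base.params, RatioGrid.base(step=2.0), seed=2,
        )
        assert (rows["qaly_delta_vs_base"] == 0.0).all()
        assert (rows["optimal_ratio"] == rows["base_optimal_ratio"]).all()

    def test_chronic_utility_has_small_qaly_impact(self, small_base):
        rows = one_way_sensitivity(
            "utilities.cteph", 0.55, 0.75, small_base.cohort, small_base.surrogate,
            small_base.params, RatioGrid.base(step=2.0), seed=2,
        )
        base_q = rows["qalys_at_optimum"].iloc[0] - rows["qaly_delta_vs_base"].iloc[0]
        assert (rows["qaly_delta_vs_base"].abs() / base_q < 0.001).all()

    def test_unknown_parameter_lists_valid_names(self, small_base):
        with pytest.raises(KeyError, match="utilities.baseline"):
            one_way_sensitivity(
                "utilities.bogus", 0.1, 0.2, small_base.cohort, small_base.surrogate,
                small_base.params, RatioGrid.base(step=2.0), seed=2,
            )


class TestScenarios:
    def test_overrides_are_applied(self):
        base = ModelParams()
        reduced = scenario_params(ScenarioConfig(scenario="reduced_dose"), base)
        assert reduced.effect.hr_vte == 0.20 and reduced.effect.hr_bleed == 1.2
        disc = scenario_params(ScenarioConfig(scenario="discontinuation"), base)
        assert disc.behavior.p_discontinue_cycle == pytest.approx(1 - 0.9**0.25)
        disut = scenario_params(ScenarioConfig(scenario="treatment_disutility"), base)
        assert disut.utilities.treatment_multiplier == 0.99
        uniform = scenario_params(ScenarioConfig(scenario="uniform_mortality"), base)
        assert uniform.mortality.beta_age_per_decade == 0.0
        assert uniform.mortality.beta_male == 0.0

    def test_null_discontinuation_equals_base_case(self, small_base):
        base_res = run_scenario(
            ScenarioConfig(scenario="base_full_dose", reps=2),
            small_base.cohort, small_base.surrogate, small_base.params, master_seed=4,
            sampling=fixed_spec(),
        )
        null_disc = run_scenario(
            ScenarioConfig(scenario="discontinuation", reps=2, p_discontinue_cycle=0.0),
            small_base.cohort, small_base.surrogate, small_base.params, master_seed=4,
            sampling=fixed_spec(),
        )
        np.testing.assert_array_equal(base_res.qalys, null_disc.qalys)

    def test_uniform_mortality_spares_lives(self, small_base):
        """Removing age/sex gradients at a fixed mean keeps expected deaths level;
        the spread of per-patient mortality is what the scenario removes."""
        params = scenario_params(ScenarioConfig(scenario="uniform_mortality"), small_base.params)
        from vte_sim.risk import MortalityModel

        m = MortalityModel(shape=params.mortality.shape, beta_age_per_decade=0.0, beta_male=0.0,
                           target_5y=params.mortality.target_5y_mortality)
        m.calibrate(small_base.cohort)
        mort5 = m.five_year_mortality(small_base.cohort)
        assert np.ptp(mort5) < 1e-12  # same death rate for all patients
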