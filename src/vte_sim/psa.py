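"""Ratio sweep, optimal-ratio determination, probabilistic and scenario analyses.

The QALY-optimal benefit–harm ratio is the grid ratio whose assignment
yields the most QALYs over the 5-year horizon (argmax; ties go to the
lowest ratio).  The probabilistic analysis repeats the full ratio sweep
with probabilities, utilities and treatment effects drawn from their
uncertainty distributions (probabilities → beta parameterised by mean and
effective sample size; hazard ratios → log-normal around the base value;
disutilities → gamma with fixed coefficient of variation); the final
optimal-ratio estimate is the mean of per-replication argmax ratios with a
2.5/97.5 percentile interval.  All ratios, the guideline arm and all
replications share one set of per-patient uniforms — common random
numbers — so differences across ratios reflect assignment only and
differences across replications reflect parameter uncertainty only
(degenerate distributions reproduce the same result in every
replication).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .microsim import RunResult, cycle_uniforms, simulate_cohort
from .params import ModelParams, get_param, param_names, set_param
from .policies import RatioGrid, accp_bleeding_score, guideline_policy, prune_grid, ratio_policy
from .risk import MortalityModel, SurrogateRiskModel, TreatmentEffect, predict_5y_risks

__all__ = [
    "ParamDistribution",
    "SamplingSpec",
    "default_sampling_spec",
    "sample_params",
    "sweep_ratios",
    "optimal_ratio",
    "PSAResult",
    "run_psa",
    "one_way_sensitivity",
    "ScenarioConfig",
    "run_scenario",
]


class ParamDistribution(BaseModel):
    """Uncertainty distribution for one model parameter.

    ``beta_mean_ess`` treats the base value as the mean of a beta with the
    given effective sample size; ``lognormal`` treats it as the median
    with the given log-scale sigma; ``gamma_cv`` as a gamma mean with
    fixed coefficient of variation.
    """

    kind: Literal["beta_mean_ess", "lognormal", "gamma_cv", "fixed"]
    ess: float | None = Field(default=None, gt=0)
    sigma: float | None = Field(default=None, gt=0)
    cv: float | None = Field(default=None, gt=0)

    def sample(self, mean: float, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return mean
        if self.kind == "beta_mean_ess":
            if not 0 < mean < 1:
                return mean
            a = mean * self.ess
            b = (1.0 - mean) * self.ess
            return float(rng.beta(a, b))
        if self.kind == "lognormal":
            return float(mean * np.exp(rng.normal(0.0, self.sigma)))
        # gamma_cv
        if mean <= 0:
            return mean
        shape = 1.0 / self.cv**2
        return float(rng.gamma(shape, mean * self.cv**2))


class SamplingSpec(BaseModel):
    """Dotted parameter name -> uncertainty distribution."""

    distributions: dict[str, ParamDistribution]


def default_sampling_spec() -> SamplingSpec:
    beta = lambda ess: ParamDistribution(kind="beta_mean_ess", ess=ess)  # noqa: E731
    return SamplingSpec(
        distributions={
            "effect.hr_vte": ParamDistribution(kind="lognormal", sigma=0.25),
            "effect.hr_bleed": ParamDistribution(kind="lognormal", sigma=0.20),
            "events.cf_pe": beta(200),
            "events.cf_major_bleed": beta(200),
            "events.cf_ich": beta(100),
            "events.p_crnmb_given_bleed": beta(100),
            "events.p_ich_given_major": beta(100),
            "events.p_pts_after_dvt": beta(100),
            "events.p_cteph_after_pe": beta(200),
            "events.p_postich_after_ich": beta(50),
            "utilities.baseline": beta(200),
            "utilities.pts": beta(100),
            "utilities.cteph": beta(100),
            "utilities.post_ich": beta(100),
            "utilities.dis_pe": ParamDistribution(kind="gamma_cv", cv=0.3),
            "utilities.dis_dvt": ParamDistribution(kind="gamma_cv", cv=0.3),
            "utilities.dis_major_bleed": ParamDistribution(kind="gamma_cv", cv=0.3),
            "utilities.dis_crnmb": ParamDistribution(kind="gamma_cv", cv=0.3),
            "mortality.target_5y_mortality": beta(20),
        }
    )


def sample_params(
    base: ModelParams, spec: SamplingSpec, rng: np.random.Generator
) -> ModelParams:
    """Draw one parameter set; unlisted parameters stay at their base value."""
    valid = set(param_names(base))
    out = base
    for name, dist in spec.distributions.items():
        if name not in valid:
            raise KeyError(
                f"sampling spec refers to unknown parameter '{name}'; "
                f"valid names: {', '.join(sorted(valid))}"
            )
        out = set_param(out, name, dist.sample(get_param(base, name), rng))
    return out


def _effect(params: ModelParams) -> TreatmentEffect:
    return TreatmentEffect(
        hr_vte=params.effect.hr_vte,
        hr_bleed=params.effect.hr_bleed,
        label=params.effect.label,
    )


def sweep_ratios(
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    grid: RatioGrid,
    mort_cycle: np.ndarray,
    params: ModelParams,
    seed: int,
    prune: bool = True,
) -> pd.DataFrame:
    """One microsimulation run per grid ratio under common random numbers.

    Returns a tidy frame with one row per (pruned) ratio: proportion
    treated, event counts, deaths and total QALYs.
    """
    if prune:
        grid = prune_grid(profiles, grid)
    uniforms = cycle_uniforms(seed, cohort["id"].to_numpy())
    rows = []
    for r in grid:
        treated = ratio_policy(profiles, r)
        res = simulate_cohort(
            profiles, treated, mort_cycle, params, uniforms, label=f"ratio={r:g}"
        )
        rows.append(_result_row(r, res))
    return pd.DataFrame(rows)


def _result_row(r: float, res: RunResult) -> dict:
    return {
        "ratio": r,
        "proportion_treated": res.proportion_treated,
        "recurrences": res.recurrences,
        "bleeds": res.bleeds,
        "deaths": res.deaths,
        "qalys": res.qalys,
    }


def optimal_ratio(sweep: pd.DataFrame) -> float:
    """Ratio with the highest total QALYs; ties break to the lowest ratio."""
    if len(sweep) == 0:
        raise ValueError("empty ratio sweep")
    ordered = sweep.sort_values("ratio", kind="stable")
    return float(ordered["ratio"].iloc[int(np.argmax(ordered["qalys"].to_numpy()))])


@dataclass
class PSAResult:
    """Probabilistic-analysis output across Monte Carlo replications."""

    grid: np.ndarray  # ratios, after pruning on the base-case profiles
    per_rep_optimal: np.ndarray  # (reps,)
    per_rep_optimal_qalys: np.ndarray  # (reps,)
    qalys: np.ndarray  # (reps, n_ratios)
    recurrences: np.ndarray
    bleeds: np.ndarray
    deaths: np.ndarray
    proportion_treated: np.ndarray
    soc_qalys: np.ndarray | None = None  # guideline arm, same random numbers
    soc_result: dict | None = None

    @property
    def reps(self) -> int:
        return len(self.per_rep_optimal)

    @property
    def mean_optimal_ratio(self) -> float:
        return float(self.per_rep_optimal.mean())

    @property
    def optimal_ratio_ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.per_rep_optimal, [2.5, 97.5])
        return float(lo), float(hi)

    def convergence_trace(self) -> pd.DataFrame:
        """Running mean of the optimal ratio by replication index."""
        running = np.cumsum(self.per_rep_optimal) / np.arange(1, self.reps + 1)
        return pd.DataFrame(
            {"replication": np.arange(1, self.reps + 1), "running_mean_optimal": running}
        )

    def per_ratio_means(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio": self.grid,
                "proportion_treated": self.proportion_treated.mean(axis=0),
                "recurrences": self.recurrences.mean(axis=0),
                "bleeds": self.bleeds.mean(axis=0),
                "deaths": self.deaths.mean(axis=0),
                "qalys": self.qalys.mean(axis=0),
            }
        )

    def summary(self) -> dict:
        lo, hi = self.optimal_ratio_ci
        out = {
            "replications": self.reps,
            "mean_optimal_ratio": self.mean_optimal_ratio,
            "optimal_ratio_ci": [lo, hi],
            "mean_optimal_qalys": float(self.per_rep_optimal_qalys.mean()),
        }
        if self.soc_qalys is not None:
            out["mean_soc_qalys"] = float(self.soc_qalys.mean())
        return out


def run_psa(
    cohort: pd.DataFrame,
    surrogate: SurrogateRiskModel,
    base_params: ModelParams,
    grid: RatioGrid,
    reps: int,
    master_seed: int,
    sampling: SamplingSpec | None = None,
    include_soc: bool = True,
) -> PSAResult:
    """Monte Carlo probabilistic analysis of the full ratio sweep.

    Per replication: draw a parameter set, rebuild on-treatment risks from
    the drawn hazard ratios, recalibrate background mortality to the drawn
    5-year target, run the microsimulation at every grid ratio (and the
    guideline arm) with shared uniforms, and record the argmax-QALY ratio.
    The grid is pruned once on the base-case (undrawn) profiles so all
    replications share a common ratio axis.
    """
    if reps < 2:
        raise ValueError("at least 2 replications are required")
    sampling = sampling if sampling is not None else default_sampling_spec()

    base_profiles = predict_5y_risks(cohort, surrogate, _effect(base_params))
    grid = prune_grid(base_profiles, grid)
    values = np.asarray(list(grid), dtype=float)
    ids = cohort["id"].to_numpy()

    soc_treated = guideline_policy(cohort, accp_bleeding_score(cohort)[1]) if include_soc else None

    n_r = len(values)
    qalys = np.empty((reps, n_r))
    recs = np.empty((reps, n_r))
    bleeds = np.empty((reps, n_r))
    deaths = np.empty((reps, n_r))
    props = np.empty((reps, n_r))
    opt = np.empty(reps)
    opt_q = np.empty(reps)
    soc_q = np.empty(reps) if include_soc else None
    soc_acc = {"recurrences": 0.0, "bleeds": 0.0, "deaths": 0.0, "qalys": 0.0,
               "proportion_treated": 0.0}

    seq = np.random.SeedSequence(master_seed)
    uniforms = cycle_uniforms(int(seq.generate_state(1, np.uint32)[0]), ids)
    children = seq.spawn(reps)
    for i, child in enumerate(children):
        param_rng = np.random.default_rng(child)
        drawn = sample_params(base_params, sampling, param_rng)
        profiles = predict_5y_risks(cohort, surrogate, _effect(drawn))
        mort = MortalityModel(
            shape=drawn.mortality.shape,
            beta_age_per_decade=drawn.mortality.beta_age_per_decade,
            beta_male=drawn.mortality.beta_male,
            target_5y=drawn.mortality.target_5y_mortality,
        )
        mort.calibrate(cohort)
        mort_cycle = mort.cycle_probs(cohort)

        for j, r in enumerate(values):
            treated = ratio_policy(profiles, r)
            res = simulate_cohort(profiles, treated, mort_cycle, drawn, uniforms)
            qalys[i, j] = res.qalys
            recs[i, j] = res.recurrences
            bleeds[i, j] = res.bleeds
            deaths[i, j] = res.deaths
            props[i, j] = res.proportion_treated

        best = int(np.argmax(qalys[i]))
        opt[i] = values[best]
        opt_q[i] = qalys[i, best]

        if include_soc:
            res = simulate_cohort(profiles, soc_treated, mort_cycle, drawn, uniforms,
                                  label="standard_of_care")
            soc_q[i] = res.qalys
            soc_acc["recurrences"] += res.recurrences
            soc_acc["bleeds"] += res.bleeds
            soc_acc["deaths"] += res.deaths
            soc_acc["qalys"] += res.qalys
            soc_acc["proportion_treated"] += res.proportion_treated

    soc_result = None
    if include_soc:
        soc_result = {k: v / reps for k, v in soc_acc.items()}
    return PSAResult(
        grid=values,
        per_rep_optimal=opt,
        per_rep_optimal_qalys=opt_q,
        qalys=qalys,
        recurrences=recs,
        bleeds=bleeds,
        deaths=deaths,
        proportion_treated=props,
        soc_qalys=soc_q,
        soc_result=soc_result,
    )


def one_way_sensitivity(
    param_name: str,
    low: float,
    high: float,
    cohort: pd.DataFrame,
    surrogate: SurrogateRiskModel,
    base_params: ModelParams,
    grid: RatioGrid,
    seed: int,
) -> pd.DataFrame:
    """Tornado rows: deterministic sweep with one parameter at each bound.

    Returns one row per bound with the resulting optimal ratio, total
    QALYs at the optimum, and the QALY delta versus the base-value sweep.
    """
    if low > high:
        raise ValueError("low bound must not exceed high bound")
    get_param(base_params, param_name)  # raises KeyError listing valid names

    def _sweep_with(value: float) -> tuple[float, float]:
        p = set_param(base_params, param_name, value)
        profiles = predict_5y_risks(cohort, surrogate, _effect(p))
        mort = MortalityModel(
            shape=p.mortality.shape,
            beta_age_per_decade=p.mortality.beta_age_per_decade,
            beta_male=p.mortality.beta_male,
            target_5y=p.mortality.target_5y_mortality,
        )
        mort.calibrate(cohort)
        sweep = sweep_ratios(cohort, profiles, grid, mort.cycle_probs(cohort), p, seed)
        best = optimal_ratio(sweep)
        return best, float(sweep.loc[sweep["ratio"] == best, "qalys"].iloc[0])

    base_value = float(get_param(base_params, param_name))
    base_opt, base_q = _sweep_with(base_value)
    rows = []
    for bound, value in (("low", low), ("high", high)):
        opt, q = _sweep_with(value)
        rows.append(
            {
                "parameter": param_name,
                "bound": bound,
                "value": value,
                "optimal_ratio": opt,
                "qalys_at_optimum": q,
                "qaly_delta_vs_base": q - base_q,
                "base_optimal_ratio": base_opt,
            }
        )
    return pd.DataFrame(rows)


ScenarioId = Literal[
    "base_full_dose",
    "reduced_dose",
    "discontinuation",
    "treatment_disutility",
    "uniform_mortality",
]


class ScenarioConfig(BaseModel):
    """One of the predefined scenario analyses."""

    scenario: ScenarioId = "base_full_dose"
    reps: int = Field(default=400, ge=2)
    #: per-cycle random discontinuation probability (discontinuation scenario);
    #: the default is the per-cycle equivalent of 10% per year
    p_discontinue_cycle: float = Field(default=1.0 - 0.9**0.25, ge=0, le=1)
    treatment_multiplier: float = Field(default=0.99, gt=0, le=1)
    grid_hi: float = Field(default=50.0, gt=0)


def scenario_params(config: ScenarioConfig, base: ModelParams) -> ModelParams:
    """Apply a scenario's overrides to a base parameter set."""
    data = base.model_dump()
    if config.scenario == "reduced_dose":
        data["effect"] = {"hr_vte": 0.20, "hr_bleed": 1.2, "label": "reduced_dose_doac"}
    elif config.scenario == "discontinuation":
        data["behavior"]["p_discontinue_cycle"] = config.p_discontinue_cycle
    elif config.scenario == "treatment_disutility":
        data["utilities"]["treatment_multiplier"] = config.treatment_multiplier
    elif config.scenario == "uniform_mortality":
        data["mortality"]["beta_age_per_decade"] = 0.0
        data["mortality"]["beta_male"] = 0.0
    return ModelParams.model_validate(data)


def run_scenario(
    config: ScenarioConfig,
    cohort: pd.DataFrame,
    surrogate: SurrogateRiskModel,
    base_params: ModelParams,
    master_seed: int,
    sampling: SamplingSpec | None = None,
) -> PSAResult:
    """Probabilistic analysis under one scenario's parameter overrides.

    The reduced-dose scenario extends the ratio grid upward (the smaller
    bleeding-harm excess shifts the informative ratio range to much larger
    values); replication count defaults to 400.
    """
    params = scenario_params(config, base_params)
    hi = config.grid_hi if config.scenario == "reduced_dose" else 10.0
    grid = RatioGrid.base(hi=hi)
    return run_psa(
        cohort, surrogate, params, grid, config.reps, master_seed, sampling=sampling
    )
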