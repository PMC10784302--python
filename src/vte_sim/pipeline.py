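"""High-level convenience assembly of the base-case analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .params import ModelParams
from .risk import MortalityModel, SurrogateRiskModel, calibrate_surrogate, predict_5y_risks
from .risk import TreatmentEffect

__all__ = ["BaseCase", "build_base_case"]


@dataclass
class BaseCase:
    """Calibrated inputs shared by all downstream analyses."""

    cohort: pd.DataFrame
    surrogate: SurrogateRiskModel
    params: ModelParams
    mortality: MortalityModel
    profiles: pd.DataFrame  # risks under the base-case treatment effect

    @property
    def mort_cycle(self) -> np.ndarray:
        return self.mortality.cycle_probs(self.cohort)


def build_base_case(
    seed: int, n: int = 10_000, params: ModelParams | None = None
) -> BaseCase:
    """Generate the cohort, calibrate risks and mortality, predict profiles."""
    params = params if params is not None else ModelParams()
    cohort = generate_cohort(CohortSpec(n=n, seed=seed))
    surrogate = calibrate_surrogate(cohort)
    effect = TreatmentEffect(
        hr_vte=params.effect.hr_vte,
        hr_bleed=params.effect.hr_bleed,
        label=params.effect.label,
    )
    profiles = predict_5y_risks(cohort, surrogate, effect)
    mortality = MortalityModel(
        shape=params.mortality.shape,
        beta_age_per_decade=params.mortality.beta_age_per_decade,
        beta_male=params.mortality.beta_male,
        target_5y=params.mortality.target_5y_mortality,
    )
    mortality.calibrate(cohort)
    return BaseCase(
        cohort=cohort,
        surrogate=surrogate,
        params=params,
        mortality=mortality,
        profiles=profiles,
    )
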