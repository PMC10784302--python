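"""Model parameters: event probabilities, utilities, mortality, behavior.

All values are config-exposed literature-informed defaults; every numeric
field can be varied in one-way sensitivity analysis and sampled in the
probabilistic analysis.  Parameters are addressed by dotted names, e.g.
``utilities.baseline`` or ``effect.hr_vte``.
"""

from __future__ import annotations

from typing import Any

import yaml
from pydantic import BaseModel, Field

__all__ = [
    "EventParams",
    "Utilities",
    "MortalityParams",
    "EffectParams",
    "BehaviorParams",
    "ModelParams",
    "get_param",
    "set_param",
    "param_names",
]


class EventParams(BaseModel):
    """Conditional event probabilities (per event, not per cycle)."""

    p_crnmb_given_bleed: float = Field(default=0.70, ge=0, le=1)
    p_ich_given_major: float = Field(default=0.15, ge=0, le=1)
    cf_pe: float = Field(default=0.05, ge=0, le=1)  # case fatality, recurrent PE
    cf_major_bleed: float = Field(default=0.08, ge=0, le=1)  # non-ICH major bleed
    cf_ich: float = Field(default=0.40, ge=0, le=1)
    p_pts_after_dvt: float = Field(default=0.25, ge=0, le=1)
    p_cteph_after_pe: float = Field(default=0.03, ge=0, le=1)
    p_postich_after_ich: float = Field(default=0.60, ge=0, le=1)
    p_pe_given_recurrence: float = Field(default=0.48, ge=0, le=1)


class Utilities(BaseModel):
    """Health-state utilities and one-cycle acute disutilities."""

    baseline: float = Field(default=0.85, ge=0, le=1)
    pts: float = Field(default=0.75, ge=0, le=1)
    cteph: float = Field(default=0.65, ge=0, le=1)
    post_ich: float = Field(default=0.55, ge=0, le=1)
    dis_pe: float = Field(default=0.20, ge=0)
    dis_dvt: float = Field(default=0.15, ge=0)
    dis_major_bleed: float = Field(default=0.20, ge=0)
    dis_crnmb: float = Field(default=0.05, ge=0)
    #: multiplier applied to each on-treatment cycle's utility (scenario)
    treatment_multiplier: float = Field(default=1.0, gt=0, le=1)


class MortalityParams(BaseModel):
    """Background Weibull mortality configuration."""

    shape: float = Field(default=1.2, gt=0)
    beta_age_per_decade: float = 0.7
    beta_male: float = 0.3
    target_5y_mortality: float = Field(default=0.106, gt=0, lt=1)


class EffectParams(BaseModel):
    """Extended-anticoagulation effect (proportional hazards on 5-y risk)."""

    hr_vte: float = Field(default=0.15, gt=0)
    hr_bleed: float = Field(default=2.0, gt=0)
    label: str = "full_dose_doac"


class BehaviorParams(BaseModel):
    """Treatment dynamics during follow-up."""

    #: stop anticoagulation permanently after an on-treatment major bleed
    stop_after_major_bleed: bool = True
    #: restart anticoagulation after an off-treatment recurrence
    restart_after_recurrence: bool = True
    #: per-cycle probability of random, permanent discontinuation (scenario)
    p_discontinue_cycle: float = Field(default=0.0, ge=0, le=1)


class ModelParams(BaseModel):
    """Complete parameter set for a simulation run."""

    events: EventParams = Field(default_factory=EventParams)
    utilities: Utilities = Field(default_factory=Utilities)
    mortality: MortalityParams = Field(default_factory=MortalityParams)
    effect: EffectParams = Field(default_factory=EffectParams)
    behavior: BehaviorParams = Field(default_factory=BehaviorParams)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def param_names(params: ModelParams) -> list[str]:
    """Dotted names of all numeric parameters."""
    names: list[str] = []
    for section, model in params:
        if not isinstance(model, BaseModel):
            continue
        for name, value in model:
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                names.append(f"{section}.{name}")
    return names


def get_param(params: ModelParams, dotted: str) -> Any:
    section, _, name = dotted.partition(".")
    try:
        return getattr(getattr(params, section), name)
    except AttributeError:
        raise KeyError(
            f"unknown parameter '{dotted}'; valid names: {', '.join(param_names(params))}"
        ) from None


def set_param(params: ModelParams, dotted: str, value: Any) -> ModelParams:
    """Return a copy of ``params`` with one dotted parameter replaced."""
    get_param(params, dotted)  # raises KeyError with the valid-name list
    section, _, name = dotted.partition(".")
    data = params.model_dump()
    data[section][name] = value
    return ModelParams.model_validate(data)
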