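"""Treatment-assignment policies.

Two strategies are implemented:

* the ratio rule — extend anticoagulation when the predicted absolute
  recurrence risk reduction strictly outweighs the predicted absolute
  bleeding risk increase weighted by a ratio r (``arr > r * ari``); r is
  the severity of one clinically relevant bleed relative to one recurrent
  VTE;
* guideline standard of care — extend treatment for unprovoked or
  minor-provoked (estrogen) index events, or a VTE history without a major
  transient provoking factor, unless the ACCP bleeding-risk category is
  high (>= 2 risk factors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RatioGrid",
    "AccpConfig",
    "ratio_policy",
    "accp_bleeding_score",
    "guideline_policy",
    "assignment_curve",
    "prune_grid",
]


@dataclass(frozen=True)
class RatioGrid:
    """Ordered grid of benefit–harm ratios."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) == 0:
            raise ValueError("ratio grid is empty")
        if np.any(v <= 0):
            raise ValueError("all ratios must be positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("ratio grid must be strictly increasing")

    @classmethod
    def base(cls, lo: float = 0.10, hi: float = 10.0, step: float = 0.10) -> "RatioGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(tuple(np.round(lo + step * np.arange(n), 10)))

    @classmethod
    def extended(cls, hi: float = 50.0) -> "RatioGrid":
        """Base grid stretched upward for scenarios with larger benefit–harm ratios."""
        return cls.base(hi=hi)

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def ratio_policy(profiles: pd.DataFrame, r: float) -> np.ndarray:
    """Treat iff ``arr > r * ari`` (strict; ties are not treated).

    Patients with ``ari == 0`` are treated whenever ``arr > 0`` at any
    ratio (the limit of the rule).
    """
    if r <= 0:
        raise ValueError("ratio must be positive")
    arr = np.asarray(profiles["arr"], dtype=float)
    ari = np.asarray(profiles["ari"], dtype=float)
    return arr > r * ari


@dataclass(frozen=True)
class AccpConfig:
    """Thresholds for the ACCP bleeding-risk factor count.

    Factors present in this cohort: age > 65 (one extra factor when > 75),
    prior bleeding, prior stroke, diabetes, anemia (sex-specific hemoglobin
    threshold), renal insufficiency, thrombocytopenia, antiplatelet
    therapy, NSAID use.  Cancer / liver disease / alcohol abuse / recent
    surgery are structurally absent but counted if present in the data.
    """

    age_threshold: float = 65.0
    age_high_threshold: float = 75.0
    hb_male: float = 13.0
    hb_female: float = 12.0
    egfr_threshold: float = 60.0
    platelet_threshold: float = 150.0
    high_category_score: int = 2


_REQUIRED_ACCP = [
    "age",
    "sex",
    "hb",
    "egfr",
    "platelets",
    "prior_bleeding",
    "prior_stroke",
    "diabetes",
    "antiplatelet",
    "nsaid",
]


def accp_bleeding_score(
    cohort: pd.DataFrame, config: AccpConfig = AccpConfig()
) -> tuple[pd.Series, pd.Series]:
    """ACCP bleeding-risk factor count and category per patient.

    Returns ``(score, category)``; category is ``low`` (0 factors),
    ``moderate`` (1) or ``high`` (>= 2).
    """
    for col in _REQUIRED_ACCP:
        if col not in cohort.columns:
            raise ValueError(f"missing covariate '{col}' required for the ACCP score")
    female = cohort["sex"] == "female"
    age = cohort["age"]
    hb_thresh = np.where(female, config.hb_female, config.hb_male)
    score = (
        (age > config.age_threshold).astype(int)
        + (age > config.age_high_threshold).astype(int)
        + cohort["prior_bleeding"].astype(int)
        + cohort["prior_stroke"].astype(int)
        + cohort["diabetes"].astype(int)
        + (cohort["hb"] < hb_thresh).astype(int)
        + (cohort["egfr"] < config.egfr_threshold).astype(int)
        + (cohort["platelets"] < config.platelet_threshold).astype(int)
        + cohort["antiplatelet"].astype(int)
        + cohort["nsaid"].astype(int)
    )
    for extra in ("history_cancer", "liver_disease", "alcohol_abuse", "recent_surgery"):
        if extra in cohort.columns:
            score = score + cohort[extra].astype(int)
    category = pd.Series(
        np.select(
            [score >= config.high_category_score, score == 1],
            ["high", "moderate"],
            default="low",
        ),
        index=cohort.index,
    )
    return score.rename("accp_score"), category.rename("accp_category")


def guideline_policy(cohort: pd.DataFrame, category: pd.Series | None = None) -> np.ndarray:
    """Guideline standard of care: treated flag per patient.

    Treated iff the index event is unprovoked or provoked by a minor
    (estrogen) factor, or there is a VTE history with a non-major-provoked
    index event, AND the ACCP bleeding-risk category is not high.  Surgery /
    trauma / immobilization is the only major transient category.
    """
    if category is None:
        _, category = accp_bleeding_score(cohort)
    provocation = cohort["provocation"]
    not_major = provocation != "surgery"
    eligible = not_major | (cohort["history_vte"].astype(bool) & not_major)
    return (eligible & (category != "high")).to_numpy()


def assignment_curve(profiles: pd.DataFrame, grid: RatioGrid) -> pd.DataFrame:
    """Proportion treated by the ratio rule at every grid ratio.

    The proportion is non-increasing in r: raising the ratio weights
    bleeding more heavily, so fewer patients clear the bar.
    """
    rows = [
        {"ratio": r, "proportion_treated": float(ratio_policy(profiles, r).mean())}
        for r in grid
    ]
    return pd.DataFrame(rows)


def prune_grid(profiles: pd.DataFrame, grid: RatioGrid) -> RatioGrid:
    """Drop uninformative ratios at the ends of the grid.

    Ratios below the largest all-treated ratio and above the smallest
    none-treated ratio are removed (assignment, hence outcomes, are
    constant beyond those points).
    """
    curve = assignment_curve(profiles, grid)
    props = curve["proportion_treated"].to_numpy()
    values = curve["ratio"].to_numpy()
    all_treated = np.flatnonzero(props == 1.0)
    none_treated = np.flatnonzero(props == 0.0)
    lo_idx = all_treated.max() if len(all_treated) else 0
    hi_idx = none_treated.min() if len(none_treated) else len(values) - 1
    kept = values[lo_idx : hi_idx + 1]
    if len(kept) == 0:
        raise ValueError("ratio grid is empty after pruning")
    return RatioGrid(tuple(kept))
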