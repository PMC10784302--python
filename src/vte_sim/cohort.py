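"""Synthetic post-VTE cohort generation.

Generates virtual patients whose marginal covariate distribution matches the
published baseline table of a prospective post-anticoagulation VTE cohort
(n = 10,000 simulated patients; mean age 60.2, 36% female, 89% unprovoked
index events).  Covariates are sampled independently given the marginals,
with two structural constraints:

* estrogen-provoked index events occur only in women;
* provoked index events imply a history of VTE (the source cohort enrolled
  unprovoked VTE or provoked VTE with a VTE history); the history prevalence
  among unprovoked patients is adjusted so the overall marginal is preserved.

Continuous covariates are truncated normals with physiological bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

__all__ = [
    "ContinuousMarginal",
    "CohortSpec",
    "Patient",
    "generate_cohort",
    "summarize_cohort",
    "write_cohort",
    "read_cohort",
    "BINARY_COLUMNS",
    "CONTINUOUS_COLUMNS",
    "COHORT_COLUMNS",
]

#: binary covariate columns, stored as 0/1 integers
BINARY_COLUMNS = [
    "smoker",
    "prior_stroke",
    "prior_bleeding",
    "history_vte",
    "cvd",
    "diabetes",
    "antiplatelet",
    "nsaid",
    "history_cancer",
    "liver_disease",
    "alcohol_abuse",
    "recent_surgery",
    "pregnancy",
]

CONTINUOUS_COLUMNS = ["age", "bmi", "sbp", "hb", "egfr", "platelets"]

CATEGORICAL_COLUMNS = ["sex", "index_event", "provocation"]

COHORT_COLUMNS = ["id"] + CATEGORICAL_COLUMNS + BINARY_COLUMNS + CONTINUOUS_COLUMNS

#: covariates forced absent: exclusion criteria of the source cohort
STRUCTURAL_ZEROS = [
    "history_cancer",
    "liver_disease",
    "alcohol_abuse",
    "recent_surgery",
    "pregnancy",
]


class ContinuousMarginal(BaseModel):
    """Truncated-normal descriptor for a continuous covariate."""

    mean: float
    sd: float = Field(gt=0)
    lo: float
    hi: float

    @model_validator(mode="after")
    def _bounds_ordered(self) -> "ContinuousMarginal":
        if not self.lo < self.hi:
            raise ValueError(f"lower bound {self.lo} must be below upper bound {self.hi}")
        return self


class CohortSpec(BaseModel):
    """Distributional recipe for a synthetic cohort.

    ``binary`` maps covariate name -> prevalence; ``continuous`` maps
    covariate name -> truncated-normal marginal.  ``p_female``,
    ``p_index_pe`` and the three provocation probabilities describe the
    categorical covariates.  ``link_provoked_history`` enforces the
    inclusion constraint provoked ⇒ history of VTE.
    """

    n: int = Field(default=10_000, ge=1)
    seed: int = 0
    p_female: float = Field(default=0.3554, ge=0.0, le=1.0)
    p_index_pe: float = Field(default=0.4806, ge=0.0, le=1.0)
    p_unprovoked: float = Field(default=0.8862 / 1.0034, ge=0.0, le=1.0)
    p_estrogen: float = Field(default=0.0601 / 1.0034, ge=0.0, le=1.0)
    p_surgery: float = Field(default=0.0571 / 1.0034, ge=0.0, le=1.0)
    binary: dict[str, float] = Field(
        default_factory=lambda: {
            "smoker": 0.1137,
            "prior_stroke": 0.0307,
            "prior_bleeding": 0.0316,
            "history_vte": 0.3614,
            "cvd": 0.0511,
            "diabetes": 0.1078,
            "antiplatelet": 0.0544,
            "nsaid": 0.0346,
            "history_cancer": 0.0,
            "liver_disease": 0.0,
            "alcohol_abuse": 0.0,
            "recent_surgery": 0.0,
            "pregnancy": 0.0,
        }
    )
    continuous: dict[str, ContinuousMarginal] = Field(
        default_factory=lambda: {
            "age": ContinuousMarginal(mean=60.2, sd=14.3, lo=18, hi=100),
            "bmi": ContinuousMarginal(mean=31.0, sd=6.7, lo=15, hi=60),
            "sbp": ContinuousMarginal(mean=118.0, sd=16.3, lo=80, hi=220),
            "hb": ContinuousMarginal(mean=14.2, sd=1.5, lo=8, hi=20),
            "egfr": ContinuousMarginal(mean=82.6, sd=21.0, lo=15, hi=150),
            "platelets": ContinuousMarginal(mean=240.5, sd=65.2, lo=50, hi=600),
        }
    )
    link_provoked_history: bool = True

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of '{name}' must be in [0, 1], got {p}")
        for name in STRUCTURAL_ZEROS:
            if self.binary.get(name, 0.0) != 0.0:
                raise ValueError(f"'{name}' is structurally absent; prevalence must be 0")
        total = self.p_unprovoked + self.p_estrogen + self.p_surgery
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"provocation probabilities must sum to 1, got {total}")
        if self.p_estrogen > self.p_female + 1e-12:
            raise ValueError(
                "infeasible marginals: estrogen-provoked prevalence "
                f"{self.p_estrogen:.4f} exceeds female prevalence {self.p_female:.4f}"
            )
        if self.link_provoked_history:
            p_provoked = self.p_estrogen + self.p_surgery
            if self.binary["history_vte"] < p_provoked - 1e-12:
                raise ValueError(
                    "infeasible marginals: history_vte prevalence below provoked share"
                )
        return self


@dataclass
class Patient:
    """A single virtual patient (one cohort row)."""

    id: int
    age: float
    sex: str
    index_event: str
    provocation: str
    smoker: bool
    prior_stroke: bool
    prior_bleeding: bool
    history_vte: bool
    cvd: bool
    diabetes: bool
    antiplatelet: bool
    nsaid: bool
    bmi: float
    sbp: float
    hb: float
    egfr: float
    platelets: float

    @classmethod
    def from_row(cls, row: pd.Series) -> "Patient":
        return cls(
            id=int(row["id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            index_event=str(row["index_event"]),
            provocation=str(row["provocation"]),
            smoker=bool(row["smoker"]),
            prior_stroke=bool(row["prior_stroke"]),
            prior_bleeding=bool(row["prior_bleeding"]),
            history_vte=bool(row["history_vte"]),
            cvd=bool(row["cvd"]),
            diabetes=bool(row["diabetes"]),
            antiplatelet=bool(row["antiplatelet"]),
            nsaid=bool(row["nsaid"]),
            bmi=float(row["bmi"]),
            sbp=float(row["sbp"]),
            hb=float(row["hb"]),
            egfr=float(row["egfr"]),
            platelets=float(row["platelets"]),
        )


def _truncnorm(rng: np.random.Generator, m: ContinuousMarginal, n: int) -> np.ndarray:
    a = (m.lo - m.mean) / m.sd
    b = (m.hi - m.mean) / m.sd
    return stats.truncnorm.rvs(a, b, loc=m.mean, scale=m.sd, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample ``spec.n`` virtual patients; reproducible under ``spec.seed``.

    Returns a DataFrame with columns :data:`COHORT_COLUMNS`, one row per
    patient, flags as 0/1 integers.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    df = pd.DataFrame({"id": np.arange(n, dtype=np.int64)})

    female = rng.random(n) < spec.p_female
    df["sex"] = np.where(female, "female", "male")
    df["index_event"] = np.where(rng.random(n) < spec.p_index_pe, "pe", "dvt")

    # provocation: estrogen restricted to women; conditional probabilities
    # chosen so all three marginals are preserved in expectation
    provocation = np.full(n, "unprovoked", dtype=object)
    if spec.p_female > 0 and spec.p_estrogen > 0:
        p_estrogen_f = min(spec.p_estrogen / spec.p_female, 1.0)
        estrogen = female & (rng.random(n) < p_estrogen_f)
    else:
        estrogen = np.zeros(n, dtype=bool)
    p_surg_rest = spec.p_surgery / max(1.0 - spec.p_estrogen, 1e-12)
    surgery = ~estrogen & (rng.random(n) < p_surg_rest)
    provocation[estrogen] = "estrogen"
    provocation[surgery] = "surgery"
    df["provocation"] = provocation

    for name, p in spec.binary.items():
        if name == "history_vte" and spec.link_provoked_history:
            continue
        df[name] = (rng.random(n) < p).astype(np.int8)

    if spec.link_provoked_history:
        provoked = df["provocation"].to_numpy() != "unprovoked"
        p_prov = provoked.mean() if n else 0.0
        # preserve the overall marginal given provoked ⇒ history
        p_hist_unprov = 0.0
        if p_prov < 1.0:
            p_hist_unprov = max(
                (spec.binary["history_vte"] - spec.p_estrogen - spec.p_surgery)
                / spec.p_unprovoked
                if spec.p_unprovoked > 0
                else 0.0,
                0.0,
            )
        hist = np.where(provoked, True, rng.random(n) < p_hist_unprov)
        df["history_vte"] = hist.astype(np.int8)

    for name, marg in spec.continuous.items():
        df[name] = _truncnorm(rng, marg, n)

    return df[COHORT_COLUMNS]


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table: one row per covariate.

    Binary rows report ``count`` and ``percent``; continuous rows report
    ``mean`` and ``sd`` (unbiased).  Categorical covariates are expanded to
    one row per level.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    n = len(cohort)
    rows: list[dict] = []
    rows.append(
        {
            "covariate": "female",
            "count": int((cohort["sex"] == "female").sum()),
            "percent": 100.0 * (cohort["sex"] == "female").mean(),
        }
    )
    rows.append(
        {
            "covariate": "index_pe",
            "count": int((cohort["index_event"] == "pe").sum()),
            "percent": 100.0 * (cohort["index_event"] == "pe").mean(),
        }
    )
    for level in ("unprovoked", "estrogen", "surgery"):
        mask = cohort["provocation"] == level
        rows.append(
            {"covariate": f"provocation_{level}", "count": int(mask.sum()), "percent": 100.0 * mask.mean()}
        )
    for name in BINARY_COLUMNS:
        rows.append(
            {
                "covariate": name,
                "count": int(cohort[name].sum()),
                "percent": 100.0 * cohort[name].mean(),
            }
        )
    for name in CONTINUOUS_COLUMNS:
        rows.append(
            {
                "covariate": name,
                "mean": float(cohort[name].mean()),
                "sd": float(cohort[name].std(ddof=1)) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (header row, flags as 0/1, full float precision)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`; validates schema."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required column(s): {', '.join(missing)}")
    for col in ("sex", "index_event", "provocation"):
        allowed = {
            "sex": {"female", "male"},
            "index_event": {"pe", "dvt"},
            "provocation": {"unprovoked", "estrogen", "surgery"},
        }[col]
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown category {df[col].iloc[row]!r} in column '{col}' at data row {row}"
            )
    for col in BINARY_COLUMNS + CONTINUOUS_COLUMNS + ["id"]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero((bad | df[col].isna()).to_numpy())[0])
            raise ValueError(f"non-numeric or missing value in column '{col}' at data row {row}")
        df[col] = values
    df[BINARY_COLUMNS] = df[BINARY_COLUMNS].astype(np.int8)
    df["id"] = df["id"].astype(np.int64)
    return df[COHORT_COLUMNS]
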