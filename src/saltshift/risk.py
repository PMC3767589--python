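"""Annual first-event risk from sex- and age-band-specific logistic equations.

Each model cell (an age/sex/risk-stratum combination) gets an annual
probability of a first coronary heart disease (CHD) event and of a first
stroke from

    p = 1 / (1 + exp(-(alpha + sum_i beta_i * x_i)))

where the covariates x_i are the cell means (prevalence fractions for binary
factors).  Sex enters by stratification — separate intercepts and, where
desired, separate slopes per sex and age band — rather than as a covariate.
The CHD equation uses age, systolic blood pressure, smoking, LDL and HDL
cholesterol, diabetes and antihypertensive medication use; the stroke
equation uses the subset age, SBP, smoking and diabetes.

Intercepts (alphas) carry the population's absolute event rates and are what
calibration moves; slopes (betas) carry risk-factor associations and are
held fixed when the equations are transported between populations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "AGE_BANDS",
    "CHD_TERMS",
    "STROKE_TERMS",
    "RiskProfile",
    "RiskCoefficients",
    "annual_event_probability",
    "shift_sbp",
    "rescale_alpha",
]

#: default decade age bands covering the modelled range 35-84
AGE_BANDS: tuple[tuple[int, int], ...] = ((35, 44), (45, 54), (55, 64), (65, 74), (75, 84))

#: covariates allowed in each outcome's linear predictor (besides the intercept)
CHD_TERMS = frozenset({"age", "sbp", "smoker", "ldl", "hdl", "diabetes", "antihypertensive"})
STROKE_TERMS = frozenset({"age", "sbp", "smoker", "diabetes"})

SEXES = ("male", "female")


def band_label(band: tuple[int, int]) -> str:
    return f"{band[0]}-{band[1]}"


@dataclass(frozen=True)
class RiskProfile:
    """Cell-mean covariates for one model cell."""

    age: float
    sex: str
    sbp: float
    smoker: float
    ldl: float
    hdl: float
    diabetes: float
    antihypertensive: float

    def __post_init__(self) -> None:
        if not 35 <= self.age <= 84:
            raise ValueError(f"age must lie in [35, 84], got {self.age}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name in ("smoker", "diabetes", "antihypertensive"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} is a prevalence fraction in [0, 1], got {v}")
        for name in ("sbp", "ldl", "hdl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def covariates(self) -> dict[str, float]:
        return {
            "age": self.age,
            "sbp": self.sbp,
            "smoker": self.smoker,
            "ldl": self.ldl,
            "hdl": self.hdl,
            "diabetes": self.diabetes,
            "antihypertensive": self.antihypertensive,
        }


@dataclass(frozen=True)
class RiskCoefficients:
    """Logistic-equation parameters for one outcome.

    ``table`` maps ``(sex, age_band_label)`` to a term->value mapping that
    must include ``"intercept"``; all other terms must belong to the
    outcome's covariate set.  Bands must tile 35-84 without gaps.
    """

    outcome: str  # "chd" or "stroke"
    table: Mapping[tuple[str, str], Mapping[str, float]]
    age_bands: tuple[tuple[int, int], ...] = AGE_BANDS

    def __post_init__(self) -> None:
        if self.outcome not in ("chd", "stroke"):
            raise ValueError(f"outcome must be 'chd' or 'stroke', got {self.outcome!r}")
        allowed = CHD_TERMS if self.outcome == "chd" else STROKE_TERMS
        # bands must cover 35..84 contiguously
        bands = sorted(self.age_bands)
        if bands[0][0] != 35 or bands[-1][1] != 84:
            raise ValueError("age bands must span 35-84")
        for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
            if lo2 != hi1 + 1:
                raise ValueError(f"age bands leave a gap between {hi1} and {lo2}")
        for sex in SEXES:
            for band in bands:
                key = (sex, band_label(band))
                if key not in self.table:
                    raise ValueError(f"{self.outcome} coefficients missing cell {key}")
                terms = self.table[key]
                if "intercept" not in terms:
                    raise ValueError(f"{self.outcome} cell {key} lacks an intercept")
                extra = set(terms) - allowed - {"intercept"}
                if extra:
                    raise ValueError(
                        f"{self.outcome} equation admits covariates {sorted(allowed)}; "
                        f"cell {key} has unexpected terms {sorted(extra)}"
                    )

    def band_for(self, age: float) -> tuple[int, int]:
        for band in self.age_bands:
            if band[0] <= age <= band[1]:
                return band
        raise KeyError(f"no age band covers age {age}")

    def terms_for(self, sex: str, age: float) -> Mapping[str, float]:
        return self.table[(sex, band_label(self.band_for(age)))]

    # ---- vectorised access for the cohort engine -------------------------

    def term_grid(self, ages: np.ndarray, term: str) -> np.ndarray:
        """Value of ``term`` per (age, sex) on an integer age grid; 0 if absent."""
        out = np.zeros((len(ages), len(SEXES)))
        for j, sex in enumerate(SEXES):
            for band in self.age_bands:
                mask = (ages >= band[0]) & (ages <= band[1])
                out[mask, j] = self.table[(sex, band_label(band))].get(term, 0.0)
        return out

    # ---- serialisation ---------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome: str) -> "RiskCoefficients":
        sub = df[df["outcome"] == outcome]
        if sub.empty:
            raise ValueError(f"no coefficient rows for outcome {outcome!r}")
        bands = tuple(
            sorted(
                {tuple(int(x) for x in b.split("-")) for b in sub["age_band"].unique()}
            )
        )
        table: dict[tuple[str, str], dict[str, float]] = {}
        for row in sub.itertuples(index=False):
            table.setdefault((row.sex, row.age_band), {})[row.term] = float(row.value)
        return cls(outcome=outcome, table=table, age_bands=bands)  # type: ignore[arg-type]

    @classmethod
    def from_csv(cls, path: str | Path, outcome: str) -> "RiskCoefficients":
        """Load from long-format CSV with columns outcome,sex,age_band,term,value."""
        df = pd.read_csv(path, comment="#")
        required = {"outcome", "sex", "age_band", "term", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"coefficient CSV missing columns: {sorted(missing)}")
        return cls.from_frame(df, outcome)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"outcome": self.outcome, "sex": sex, "age_band": band, "term": term, "value": v}
            for (sex, band), terms in sorted(self.table.items())
            for term, v in sorted(terms.items())
        ]
        return pd.DataFrame(rows)


def annual_event_probability(profile: RiskProfile, coeffs: RiskCoefficients) -> float:
    """Annual first-event probability for a model cell.

    Evaluates the logistic equation at the cell-mean covariates; raises
    ``KeyError`` when no coefficient age band covers the profile's age.
    """
    terms = coeffs.terms_for(profile.sex, profile.age)
    x = profile.covariates()
    lp = terms["intercept"] + sum(v * x[t] for t, v in terms.items() if t != "intercept")
    return float(expit(lp))


def shift_sbp(profile: RiskProfile, delta: float) -> RiskProfile:
    """Return the profile with systolic blood pressure lowered by ``delta`` mmHg."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if profile.sbp - delta <= 0:
        raise ValueError("shift would make SBP non-positive")
    return replace(profile, sbp=profile.sbp - delta)


def rescale_alpha(coeffs: RiskCoefficients, factor: float) -> RiskCoefficients:
    """Multiply every cell's event odds by ``factor``, leaving slopes untouched.

    On the logistic scale this adds ln(factor) to each intercept — the
    standard way of recalibrating transported risk equations to a new
    population's absolute event rates.
    """
    if factor <= 0:
        raise ValueError(f"odds factor must be positive, got {factor}")
    shift = math.log(factor)
    new_table = {
        key: {t: (v + shift if t == "intercept" else v) for t, v in terms.items()}
        for key, terms in coeffs.table.items()
    }
    return RiskCoefficients(outcome=coeffs.outcome, table=new_table, age_bands=coeffs.age_bands)
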