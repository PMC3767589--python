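"""Daily sodium intake estimated from single-void ("spot") urine samples.

A spot urine sodium concentration by itself says little about daily intake
because urine dilution varies person to person.  The Tanaka regression works
around this: predicted 24-hour creatinine excretion (from age, weight and
height) scales the spot sodium/creatinine ratio, and a power law maps the
scaled ratio to estimated 24-hour sodium excretion.  Daily excretion is then
taken as daily consumption, the standard assumption in population surveys.

Units used throughout: spot sodium in mEq/L, spot creatinine in mg/dL,
excretion in mEq/day or mg/day (23 mg sodium per mEq), salt in g/day
(2.5 g NaCl per 1000 mg sodium, the mass ratio that makes 2000 mg sodium
equal 5 g salt).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "SODIUM_MG_PER_MEQ",
    "SALT_G_PER_1000MG_SODIUM",
    "TanakaCoefficients",
    "SpotUrineSample",
    "SodiumEstimate",
    "IntakeSummary",
    "predicted_24h_creatinine",
    "estimate_24h_sodium",
    "summarize_intake",
    "sodium_to_salt",
    "read_spot_urines",
]

#: molar mass of sodium, mg per mEq
SODIUM_MG_PER_MEQ = 23.0
#: grams of NaCl per 1000 mg of sodium (2000 mg sodium == 5 g salt)
SALT_G_PER_1000MG_SODIUM = 2.5

SPOT_URINE_COLUMNS = (
    "sex",
    "age",
    "weight_kg",
    "height_cm",
    "spot_na_meq_l",
    "spot_cr_mg_dl",
)


@dataclass(frozen=True)
class TanakaCoefficients:
    """Constants of the Tanaka spot-urine estimator.

    ``pr_cr24 = cr_age*age + cr_weight*weight + cr_height*height + cr_intercept``
    predicts 24-h urinary creatinine (mg/day); estimated 24-h sodium (mEq/day)
    is ``scale * (spot_na / (spot_cr * 10) * pr_cr24) ** exponent``.
    """

    scale: float = 21.98
    exponent: float = 0.392
    cr_age: float = -2.04
    cr_weight: float = 14.89
    cr_height: float = 16.14
    cr_intercept: float = -2244.45


@dataclass(frozen=True)
class SpotUrineSample:
    """One participant's spot-urine measurement with anthropometrics."""

    sex: Literal["male", "female"]
    age: float           # years
    weight_kg: float
    height_cm: float
    spot_na_meq_l: float
    spot_cr_mg_dl: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("age", "weight_kg", "height_cm", "spot_cr_mg_dl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.spot_na_meq_l < 0:
            raise ValueError(f"spot_na_meq_l must be >= 0, got {self.spot_na_meq_l}")


@dataclass(frozen=True)
class SodiumEstimate:
    """Estimated 24-hour sodium excretion in its three equivalent units."""

    excretion_meq_day: float

    @property
    def excretion_mg_day(self) -> float:
        return self.excretion_meq_day * SODIUM_MG_PER_MEQ

    @property
    def salt_g_day(self) -> float:
        return sodium_to_salt(self.excretion_mg_day)


@dataclass(frozen=True)
class IntakeSummary:
    """Mean estimated daily sodium consumption by sex and overall."""

    mean_mg_day: dict[str, float]  # keys: male, female, overall
    n: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in ("male", "female", "overall"):
            rows.append(
                {
                    "group": group,
                    "mean_sodium_mg_day": self.mean_mg_day[group],
                    "mean_salt_g_day": sodium_to_salt(self.mean_mg_day[group]),
                    "n": self.n.get(group, 0),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"mean_mg_day": self.mean_mg_day, "n": self.n}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def predicted_24h_creatinine(
    age: float,
    weight_kg: float,
    height_cm: float,
    coeffs: TanakaCoefficients = TanakaCoefficients(),
) -> float:
    """Predicted 24-hour urinary creatinine excretion (mg/day).

    Raises ``ValueError`` when inputs are non-positive or the linear predictor
    falls to zero or below (anthropometrics outside the regression's domain).
    """
    if age <= 0 or weight_kg <= 0 or height_cm <= 0:
        raise ValueError("age, weight and height must all be positive")
    pr_cr24 = (
        coeffs.cr_age * age
        + coeffs.cr_weight * weight_kg
        + coeffs.cr_height * height_cm
        + coeffs.cr_intercept
    )
    if pr_cr24 <= 0:
        raise ValueError(
            "predicted 24-h creatinine is non-positive "
            f"({pr_cr24:.1f} mg/day) for age={age}, weight={weight_kg} kg, "
            f"height={height_cm} cm; outside the estimator's domain"
        )
    return pr_cr24


def estimate_24h_sodium(
    sample: SpotUrineSample,
    coeffs: TanakaCoefficients = TanakaCoefficients(),
) -> SodiumEstimate:
    """Estimate one participant's 24-hour sodium excretion from a spot urine.

    The spot creatinine is converted from mg/dL to mg/L (factor 10) so the
    sodium/creatinine ratio is dimensionally consistent with the predicted
    daily creatinine.
    """
    pr_cr24 = predicted_24h_creatinine(
        sample.age, sample.weight_kg, sample.height_cm, coeffs
    )
    ratio = sample.spot_na_meq_l / (sample.spot_cr_mg_dl * 10.0)
    meq_day = coeffs.scale * (ratio * pr_cr24) ** coeffs.exponent
    return SodiumEstimate(excretion_meq_day=meq_day)


def summarize_intake(
    samples: Sequence[SpotUrineSample] | Iterable[SpotUrineSample],
    coeffs: TanakaCoefficients = TanakaCoefficients(),
    method: Literal["per_sample", "mean_concentration"] = "per_sample",
) -> IntakeSummary:
    """Aggregate spot-urine samples to mean daily sodium consumption.

    ``per_sample`` (default) estimates each participant's excretion with their
    own anthropometrics and averages the estimates.  ``mean_concentration``
    first averages concentrations and anthropometrics within each sex and
    applies the estimator once per sex; the overall mean is then the
    sample-size-weighted mean of the two sex values.
    """
    samples = list(samples)
    by_sex: dict[str, list[SpotUrineSample]] = {"male": [], "female": []}
    for s in samples:
        by_sex[s.sex].append(s)
    for sex, group in by_sex.items():
        if not group:
            raise ValueError(f"no {sex} samples; need at least one per sex")

    if method == "per_sample":
        mg = {
            sex: sum(estimate_24h_sodium(s, coeffs).excretion_mg_day for s in group)
            / len(group)
            for sex, group in by_sex.items()
        }
        overall = (
            sum(estimate_24h_sodium(s, coeffs).excretion_mg_day for s in samples)
            / len(samples)
        )
    elif method == "mean_concentration":
        mg = {}
        for sex, group in by_sex.items():
            n = len(group)
            mean_sample = SpotUrineSample(
                sex=sex,
                age=sum(s.age for s in group) / n,
                weight_kg=sum(s.weight_kg for s in group) / n,
                height_cm=sum(s.height_cm for s in group) / n,
                spot_na_meq_l=sum(s.spot_na_meq_l for s in group) / n,
                spot_cr_mg_dl=sum(s.spot_cr_mg_dl for s in group) / n,
            )
            mg[sex] = estimate_24h_sodium(mean_sample, coeffs).excretion_mg_day
        overall = sum(mg[sex] * len(by_sex[sex]) for sex in mg) / len(samples)
    else:
        raise ValueError(f"unknown method {method!r}")

    mg["overall"] = overall
    n = {sex: len(group) for sex, group in by_sex.items()}
    n["overall"] = len(samples)
    return IntakeSummary(mean_mg_day=mg, n=n)


def sodium_to_salt(sodium_mg_day: float) -> float:
    """Convert daily sodium (mg) to daily salt (g); 2000 mg sodium -> 5 g salt."""
    if sodium_mg_day < 0:
        raise ValueError(f"sodium must be >= 0, got {sodium_mg_day}")
    return sodium_mg_day * SALT_G_PER_1000MG_SODIUM / 1000.0


def read_spot_urines(path: str | Path) -> list[SpotUrineSample]:
    """Read a spot-urine table from CSV.

    Expects header columns ``sex, age, weight_kg, height_cm, spot_na_meq_l,
    spot_cr_mg_dl``; lines starting with ``#`` are provenance comments.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SPOT_URINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot-urine CSV {path} is missing columns: {', '.join(missing)}")
    return [
        SpotUrineSample(
            sex=str(row.sex),
            age=float(row.age),
            weight_kg=float(row.weight_kg),
            height_cm=float(row.height_cm),
            spot_na_meq_l=float(row.spot_na_meq_l),
            spot_cr_mg_dl=float(row.spot_cr_mg_dl),
        )
        for row in df.itertuples(index=False)
    ]


def write_spot_urines(
    samples: Sequence[SpotUrineSample], path: str | Path, header_comment: str = ""
) -> None:
    """Write spot-urine samples as CSV, optionally with a '#' provenance header."""
    df = pd.DataFrame(
        [
            {
                "sex": s.sex,
                "age": s.age,
                "weight_kg": s.weight_kg,
                "height_cm": s.height_cm,
                "spot_na_meq_l": s.spot_na_meq_l,
                "spot_cr_mg_dl": s.spot_cr_mg_dl,
            }
            for s in samples
        ]
    )
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
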