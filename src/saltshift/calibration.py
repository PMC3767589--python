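"""Calibrating the cohort model to an observed CVD death series.

Transported risk equations carry the source population's absolute event
rates in their intercepts.  Calibration finds a common odds multiplier —
applied to the CHD and stroke logistic intercepts and, on the odds scale, to
the disease-history CVD death probabilities — such that the model's
projected CVD deaths in the last observed year match the vital-statistics
target.  The observed series is first augmented with a configurable fraction
of poorly defined ("garbage" code) deaths attributable to CVD.

The search is a scalar root find (Brent bracketing, a safeguarded bisection)
on the log multiplier, justified by the monotonicity of projected CVD deaths
in the multiplier.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .model import EventLedger, ModelParameters, PopulationState, run_projection
from .risk import rescale_alpha

__all__ = [
    "VitalStatisticsSeries",
    "CalibrationResult",
    "CalibrationError",
    "adjusted_cvd_deaths",
    "apply_odds_multiplier",
    "calibrate",
]


class CalibrationError(RuntimeError):
    """The target series cannot be matched within the multiplier bounds."""


@dataclass(frozen=True)
class VitalStatisticsSeries:
    """Observed CVD deaths per year: definite plus poorly defined counts."""

    frame: pd.DataFrame  # columns: year, definite_cvd_deaths, garbage_deaths

    def __post_init__(self) -> None:
        required = {"year", "definite_cvd_deaths", "garbage_deaths"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"vital-statistics frame missing columns {sorted(missing)}")
        if (self.frame[["definite_cvd_deaths", "garbage_deaths"]] < 0).any().any():
            raise ValueError("death counts must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "VitalStatisticsSeries":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path: str | Path, header_comment: str = "") -> None:
        with open(path, "w") as fh:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, index=False)

    @property
    def last_year(self) -> int:
        return int(self.frame["year"].max())


def adjusted_cvd_deaths(series: VitalStatisticsSeries, garbage_fraction: float) -> pd.Series:
    """Definite CVD deaths plus a fraction of poorly defined deaths, per year."""
    if not 0 <= garbage_fraction <= 1:
        raise ValueError(f"garbage_fraction must lie in [0, 1], got {garbage_fraction}")
    f = series.frame
    adjusted = f["definite_cvd_deaths"] + garbage_fraction * f["garbage_deaths"]
    return pd.Series(adjusted.to_numpy(), index=f["year"].to_numpy(), name="cvd_deaths")


def _scale_probability_odds(p: np.ndarray, factor: float) -> np.ndarray:
    """Multiply the odds of probability ``p`` by ``factor`` (stays within [0, 1))."""
    return p * factor / (1.0 - p + p * factor)


def apply_odds_multiplier(params: ModelParameters, factor: float) -> ModelParameters:
    """Rescale CVD event and CVD death rates by a common odds multiplier.

    Logistic intercepts shift by ln(factor); the disease-history CVD death
    probabilities are moved on the same odds scale.  Slope coefficients and
    every non-CVD rate are untouched.
    """
    if factor <= 0:
        raise ValueError("odds multiplier must be positive")
    history = replace(
        params.history, cvd_death=_scale_probability_odds(params.history.cvd_death, factor)
    )
    return replace(
        params,
        chd_coeffs=rescale_alpha(params.chd_coeffs, factor),
        stroke_coeffs=rescale_alpha(params.stroke_coeffs, factor),
        history=history,
    )


@dataclass
class CalibrationResult:
    """Outcome of a calibration run."""

    multiplier: float
    discrepancy: float  # relative error at the last observed year
    target_year: int
    target_deaths: float
    projected_deaths: float
    mode: str
    trace: list[tuple[float, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "multiplier": self.multiplier,
            "discrepancy": self.discrepancy,
            "target_year": self.target_year,
            "target_deaths": self.target_deaths,
            "projected_deaths": self.projected_deaths,
            "mode": self.mode,
            "trace": [{"multiplier": m, "relative_difference": d} for m, d in self.trace],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _projected_cvd_deaths(
    initial: PopulationState, params: ModelParameters, last_year: int
) -> pd.Series:
    ledger: EventLedger = run_projection(initial, params, scenario=None, end=last_year + 1)
    return ledger.frame["chd_deaths"] + ledger.frame["stroke_deaths"]


def calibrate(
    initial: PopulationState,
    params: ModelParameters,
    series: VitalStatisticsSeries,
    garbage_fraction: float = 1.0,
    tolerance: float = 0.05,
    mode: str = "last_year",
    bounds: tuple[float, float] = (1.0 / 50.0, 50.0),
) -> CalibrationResult:
    """Find the odds multiplier matching projected to observed CVD deaths.

    ``mode="last_year"`` (default) solves for an exact match in the last
    observed year; ``mode="least_squares"`` minimises the squared error over
    the whole overlapping series.  Either way the reported discrepancy is the
    relative error at the last observed year, required to be below
    ``tolerance`` (default 5%).

    Raises :class:`CalibrationError` when the target cannot be bracketed
    within ``bounds`` or the achieved discrepancy exceeds the tolerance.
    """
    target = adjusted_cvd_deaths(series, garbage_fraction)
    last_year = series.last_year
    if last_year < initial.year:
        raise ValueError(
            f"vital statistics end in {last_year}, before the model start {initial.year}"
        )
    target_last = float(target.loc[last_year])
    if target_last <= 0:
        raise CalibrationError("target CVD deaths in the last observed year are zero")

    trace: list[tuple[float, float]] = []

    def rel_diff_last(m: float) -> float:
        proj = _projected_cvd_deaths(initial, apply_odds_multiplier(params, m), last_year)
        d = float(proj.loc[last_year]) / target_last - 1.0
        trace.append((m, d))
        return d

    lo, hi = bounds
    if mode == "last_year":
        f_lo, f_hi = rel_diff_last(lo), rel_diff_last(hi)
        if f_lo * f_hi > 0:
            raise CalibrationError(
                f"target of {target_last:.0f} CVD deaths in {last_year} cannot be "
                f"bracketed by multipliers in [{lo:g}, {hi:g}] "
                f"(relative differences {f_lo:+.2%} and {f_hi:+.2%})"
            )
        log_m = brentq(lambda lm: rel_diff_last(float(np.exp(lm))), np.log(lo), np.log(hi), xtol=1e-10)
        multiplier = float(np.exp(log_m))
    elif mode == "least_squares":
        overlap = [y for y in target.index if y >= initial.year]

        def sse(log_m: float) -> float:
            proj = _projected_cvd_deaths(
                initial, apply_odds_multiplier(params, float(np.exp(log_m))), last_year
            )
            return float(sum((proj.loc[y] - target.loc[y]) ** 2 for y in overlap))

        res = minimize_scalar(sse, bounds=(np.log(lo), np.log(hi)), method="bounded")
        multiplier = float(np.exp(res.x))
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")

    proj = _projected_cvd_deaths(initial, apply_odds_multiplier(params, multiplier), last_year)
    projected_last = float(proj.loc[last_year])
    discrepancy = abs(projected_last - target_last) / target_last
    result = CalibrationResult(
        multiplier=multiplier,
        discrepancy=discrepancy,
        target_year=last_year,
        target_deaths=target_last,
        projected_deaths=projected_last,
        mode=mode,
        trace=trace,
    )
    if discrepancy > tolerance:
        raise CalibrationError(
            f"calibration achieved a final-year discrepancy of {discrepancy:.2%}, "
            f"above the {tolerance:.0%} tolerance (multiplier {multiplier:.4f})"
        )
    return result
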