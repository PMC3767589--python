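"""Sodium-reduction policy scenarios and their blood-pressure dose-response.

A :class:`PolicyScenario` is a schedule of annual *increments* of sodium
reduction, each a fraction of baseline intake; the cumulative reduction is
their running (additive) sum, held constant once the schedule ends.  An
:class:`SBPEffectModel` converts grams of salt removed from the diet into a
systolic blood-pressure drop, with a steeper slope for people who are
hypertensive or at least 65 years old — the subgroup in which sodium
restriction trials show the larger effect.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .sodium import sodium_to_salt

__all__ = [
    "PolicyScenario",
    "SBPEffectModel",
    "effective_reduction_fraction",
    "cumulative_reduction",
    "sodium_reduction",
    "sbp_reduction",
    "load_scenario",
    "packaged_scenario",
]


@dataclass(frozen=True)
class SBPEffectModel:
    """Per-gram-of-salt systolic blood-pressure dose-response.

    slope_high applies to the hypertensive-or-elderly subgroup (mmHg per g
    salt), slope_low to everyone else; the elderly threshold is inclusive
    (age >= threshold).
    """

    slope_high: float = 1.87
    slope_low: float = 1.17
    elderly_age_threshold: float = 65.0

    def __post_init__(self) -> None:
        if self.slope_low < 0 or self.slope_high < self.slope_low:
            raise ValueError("require 0 <= slope_low <= slope_high")

    def slope(self, is_hypertensive: bool, age: float) -> float:
        if is_hypertensive or age >= self.elderly_age_threshold:
            return self.slope_high
        return self.slope_low


@dataclass(frozen=True)
class PolicyScenario:
    """A named schedule of annual sodium-reduction increments."""

    name: str
    annual_reduction_fractions: tuple[float, ...]
    start_year: int = 2013
    horizon: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "annual_reduction_fractions",
            tuple(float(f) for f in self.annual_reduction_fractions),
        )
        if any(f < 0 for f in self.annual_reduction_fractions):
            raise ValueError("annual reduction increments must be >= 0")
        if sum(self.annual_reduction_fractions) > 1 + 1e-12:
            raise ValueError("cumulative reduction cannot exceed the whole intake")
        if len(self.annual_reduction_fractions) > self.horizon:
            raise ValueError("schedule longer than the scenario horizon")

    @classmethod
    def from_yaml(cls, path: str | Path) -> tuple["PolicyScenario", SBPEffectModel]:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scenario = cls(
            name=raw["name"],
            annual_reduction_fractions=tuple(raw["annual_reduction_fractions"]),
            start_year=int(raw.get("start_year", 2013)),
            horizon=int(raw.get("horizon", 10)),
        )
        eff = raw.get("sbp_effect", {})
        effect = SBPEffectModel(
            slope_high=float(eff.get("slope_high", 1.87)),
            slope_low=float(eff.get("slope_low", 1.17)),
            elderly_age_threshold=float(eff.get("elderly_age_threshold", 65)),
        )
        return scenario, effect

    def to_yaml(self, path: str | Path, effect: SBPEffectModel | None = None) -> None:
        payload: dict = {
            "name": self.name,
            "start_year": self.start_year,
            "horizon": self.horizon,
            "annual_reduction_fractions": list(self.annual_reduction_fractions),
        }
        if effect is not None:
            payload["sbp_effect"] = {
                "slope_high": effect.slope_high,
                "slope_low": effect.slope_low,
                "elderly_age_threshold": effect.elderly_age_threshold,
            }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def effective_reduction_fraction(
    content_reduction: float, processed_share: float
) -> float:
    """Population intake reduction from a product-content reduction.

    A ``content_reduction`` applied only to the ``processed_share`` of intake
    that comes from processed food lowers total consumption by their product
    (e.g. a 10% content cut on the 80% processed share gives 8%).
    """
    for name, v in (("content_reduction", content_reduction), ("processed_share", processed_share)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return content_reduction * processed_share


def cumulative_reduction(scenario: PolicyScenario, year_index: int) -> float:
    """Cumulative reduction fraction in force during projection year ``year_index``.

    Additive running sum of the schedule's increments; once the schedule ends
    the reduction achieved is held constant (the projection continues without
    further intervention).
    """
    if year_index < 0:
        raise ValueError(f"year_index must be >= 0, got {year_index}")
    return float(sum(scenario.annual_reduction_fractions[: year_index + 1]))


def sodium_reduction(baseline_intake_mg_day: float, fraction: float) -> float:
    """Absolute sodium reduction (mg/day) for a fractional cut of baseline intake."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    return baseline_intake_mg_day * fraction


def sbp_reduction(
    sodium_reduction_mg_day: float,
    is_hypertensive: bool,
    age: float,
    effect: SBPEffectModel = SBPEffectModel(),
) -> float:
    """Systolic blood-pressure drop (mmHg) for a given sodium reduction.

    The sodium reduction is converted to grams of salt and multiplied by the
    subgroup's per-gram slope (high for hypertensive or age >= threshold).
    """
    if sodium_reduction_mg_day < 0:
        raise ValueError("sodium reduction must be >= 0")
    return sodium_to_salt(sodium_reduction_mg_day) * effect.slope(is_hypertensive, age)


def load_scenario(path: str | Path) -> tuple[PolicyScenario, SBPEffectModel]:
    """Read a scenario definition (and its SBP effect model) from YAML."""
    return PolicyScenario.from_yaml(path)


def packaged_scenario(name: str) -> tuple[PolicyScenario, SBPEffectModel]:
    """Load one of the scenario definitions shipped with the package.

    ``"scenario1"`` — the two-year initiative: 4% + 4%, then no further cuts.
    ``"scenario2"`` — the sustained strategy: 4% per year for ten years (40%).
    """
    fname = {"scenario1": "scenario1.yaml", "scenario2": "scenario2.yaml"}.get(name)
    if fname is None:
        raise ValueError(f"unknown packaged scenario {name!r}")
    with resources.as_file(resources.files("saltshift.data") / fname) as p:
        return PolicyScenario.from_yaml(p)
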