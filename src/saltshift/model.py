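"""Annual-cycle state-transition (Markov) cohort engine.

The population aged 35-84 is partitioned into cells by single year of age,
sex, hypertension stratum (normotensive / hypertensive untreated /
hypertensive treated) and disease state (healthy, post-MI, post-stroke,
post-both).  Each annual cycle:

* demographic-epidemiological submodel — healthy cells experience first CHD
  and first stroke events at the logistic-equation probabilities (with any
  policy-scenario SBP shift applied) and die of non-CVD causes at background
  rates;
* bridge submodel — first events pass through 1-day and, conditional on
  surviving day one, 28-day case fatality; 30-day survivors enter the
  matching chronic history state;
* disease-history submodel — survivors of earlier events incur recurrent MI
  and stroke and die of CVD or other causes at history-state-specific rates.

Propagation is deterministic expected-value arithmetic on person counts
(cell-based cohort simulation, not individual-level Monte Carlo), so runs
are exactly reproducible and the annual bookkeeping identity

    persons(t+1) + deaths(t) + aged_out(t) = persons(t) + incoming(t)

holds to floating-point rounding every cycle.  Competing exits within a
cycle are combined by a product-of-survivals decomposition: the cell's total
exit probability is 1 - prod(1 - p_k), shared among causes in proportion to
their marginal probabilities, so joint exits can never exceed the cell.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .intervention import PolicyScenario, SBPEffectModel, cumulative_reduction, sodium_reduction
from .risk import RiskCoefficients
from .sodium import sodium_to_salt

__all__ = [
    "AGES",
    "SEXES",
    "STRATA",
    "STATES",
    "PopulationState",
    "CovariateGrid",
    "BridgeParameters",
    "DiseaseHistoryParameters",
    "DemographyInputs",
    "ModelParameters",
    "EventLedger",
    "scenario_sbp_shift",
    "step_year",
    "run_projection",
    "avoided_events",
]

AGES = np.arange(35, 85)  # single years of age, 35..84 inclusive
SEXES = ("male", "female")
STRATA = ("normotensive", "hypertensive_untreated", "hypertensive_treated")
STATES = ("healthy", "post_mi", "post_stroke", "post_both")
HISTORY_STATES = STATES[1:]

N_AGE, N_SEX, N_STRATUM, N_STATE = len(AGES), len(SEXES), len(STRATA), len(STATES)

LEDGER_COLUMNS = (
    "total_deaths",
    "chd_deaths",
    "stroke_deaths",
    "other_deaths",
    "mi_events",
    "stroke_events",
    "angina_events",
)


class ParameterError(ValueError):
    """A parameter bundle is inconsistent with the cell structure."""


# --------------------------------------------------------------------------
# containers


@dataclass
class PopulationState:
    """Person counts per cell plus absorbing tallies.

    ``counts`` has shape (age, sex, stratum, state) = (50, 2, 3, 4); the dead
    and aged-out tallies are cumulative since the start of the run.
    """

    year: int
    counts: np.ndarray
    dead_chd: float = 0.0
    dead_stroke: float = 0.0
    dead_other: float = 0.0
    aged_out: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_AGE, N_SEX, N_STRATUM, N_STATE):
            raise ValueError(
                f"counts must have shape {(N_AGE, N_SEX, N_STRATUM, N_STATE)}, "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def total_persons(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(
            year=self.year,
            counts=self.counts.copy(),
            dead_chd=self.dead_chd,
            dead_stroke=self.dead_stroke,
            dead_other=self.dead_other,
            aged_out=self.aged_out,
        )


@dataclass
class CovariateGrid:
    """Cell-mean risk-factor levels.

    ``sbp`` varies by hypertension stratum (shape (age, sex, stratum)); the
    other factors are age/sex means (shape (age, sex)).  Antihypertensive
    medication use is implied by the stratum (1 in the treated stratum).
    """

    sbp: np.ndarray
    smoker: np.ndarray
    ldl: np.ndarray
    hdl: np.ndarray
    diabetes: np.ndarray

    def __post_init__(self) -> None:
        self.sbp = np.asarray(self.sbp, dtype=float)
        for name in ("smoker", "ldl", "hdl", "diabetes"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sbp.shape != (N_AGE, N_SEX, N_STRATUM):
            raise ValueError(f"sbp grid must be (age, sex, stratum), got {self.sbp.shape}")
        for name in ("smoker", "ldl", "hdl", "diabetes"):
            if getattr(self, name).shape != (N_AGE, N_SEX):
                raise ValueError(f"{name} grid must be (age, sex)")
        if (self.sbp <= 0).any() or (self.ldl <= 0).any() or (self.hdl <= 0).any():
            raise ValueError("sbp, ldl and hdl must be positive")
        for name in ("smoker", "diabetes"):
            g = getattr(self, name)
            if ((g < 0) | (g > 1)).any():
                raise ValueError(f"{name} prevalences must lie in [0, 1]")


@dataclass
class BridgeParameters:
    """30-day case fatality of a first event, by event type, age and sex.

    ``cf1_*`` is the probability of death on the day of the event; ``cf28_*``
    the probability of death in days 2-28 conditional on surviving day one.
    ``mi_fraction_of_chd`` is the share of first CHD events that are
    myocardial infarctions (the remainder present as angina, which is
    tracked but excluded from the MI ledger column).
    """

    cf1_chd: np.ndarray
    cf28_chd: np.ndarray
    cf1_stroke: np.ndarray
    cf28_stroke: np.ndarray
    mi_fraction_of_chd: float = 0.6

    def __post_init__(self) -> None:
        for name in ("cf1_chd", "cf28_chd", "cf1_stroke", "cf28_stroke"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (N_AGE, N_SEX):
                raise ValueError(f"{name} must have shape (age, sex)")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} entries must be probabilities in [0, 1]")
        if not 0 <= self.mi_fraction_of_chd <= 1:
            raise ValueError("mi_fraction_of_chd must lie in [0, 1]")


@dataclass
class DiseaseHistoryParameters:
    """Annual rates for CVD survivors, shape (age, sex, history state).

    History states are ordered (post_mi, post_stroke, post_both).  Recurrent
    events move survivors towards the post_both state; CVD and non-CVD
    deaths remove them.
    """

    recurrent_mi: np.ndarray
    recurrent_stroke: np.ndarray
    cvd_death: np.ndarray
    noncvd_death: np.ndarray

    def __post_init__(self) -> None:
        for name in ("recurrent_mi", "recurrent_stroke", "cvd_death", "noncvd_death"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (N_AGE, N_SEX, len(HISTORY_STATES)):
                raise ValueError(f"{name} must have shape (age, sex, history state)")
            if (arr < 0).any():
                raise ValueError(f"{name} rates must be non-negative")


@dataclass
class DemographyInputs:
    """Background mortality and the cohorts entering at age 35.

    ``incoming_35`` maps calendar year to per-sex counts of new 35-year-olds;
    ``incoming_stratum_split`` distributes them over hypertension strata (all
    enter healthy).
    """

    noncvd_mortality: np.ndarray  # (age, sex)
    incoming_35: Mapping[int, np.ndarray]  # year -> (sex,)
    incoming_stratum_split: np.ndarray = field(
        default_factory=lambda: np.array([0.85, 0.075, 0.075])
    )

    def __post_init__(self) -> None:
        self.noncvd_mortality = np.asarray(self.noncvd_mortality, dtype=float)
        if self.noncvd_mortality.shape != (N_AGE, N_SEX):
            raise ValueError("noncvd_mortality must have shape (age, sex)")
        if ((self.noncvd_mortality < 0) | (self.noncvd_mortality > 1)).any():
            raise ValueError("noncvd mortality rates must lie in [0, 1]")
        self.incoming_stratum_split = np.asarray(self.incoming_stratum_split, dtype=float)
        if self.incoming_stratum_split.shape != (N_STRATUM,):
            raise ValueError("incoming_stratum_split must have one entry per stratum")
        if abs(self.incoming_stratum_split.sum() - 1.0) > 1e-9:
            raise ValueError("incoming_stratum_split must sum to 1")
        self.incoming_35 = {
            int(y): np.asarray(v, dtype=float) for y, v in dict(self.incoming_35).items()
        }
        for y, v in self.incoming_35.items():
            if v.shape != (N_SEX,) or (v < 0).any():
                raise ValueError(f"incoming cohort for {y} must be non-negative per-sex counts")

    def incoming_for(self, year: int) -> np.ndarray:
        if year in self.incoming_35:
            return self.incoming_35[year]
        if not self.incoming_35:
            return np.zeros(N_SEX)
        # hold the nearest specified year's cohort constant outside the table
        nearest = min(self.incoming_35, key=lambda y: abs(y - year))
        return self.incoming_35[nearest]


@dataclass
class ModelParameters:
    """Everything step_year needs besides the population itself."""

    covariates: CovariateGrid
    chd_coeffs: RiskCoefficients
    stroke_coeffs: RiskCoefficients
    bridge: BridgeParameters
    history: DiseaseHistoryParameters
    demography: DemographyInputs
    intake_mg_day: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.0, "female": 0.0}
    )

    def validate(self) -> None:
        """Raise ParameterError if any cell's combined exit probability exceeds 1."""
        h = self.history
        exit_prob = (
            1.0
            - (1.0 - np.clip(h.cvd_death, 0, 1)) * (1.0 - np.clip(h.noncvd_death, 0, 1))
        )
        if (h.cvd_death > 1).any() or (h.noncvd_death > 1).any() or (exit_prob > 1).any():
            idx = np.argwhere((h.cvd_death > 1) | (h.noncvd_death > 1))
            a, s, st = idx[0]
            raise ParameterError(
                "disease-history exit probability exceeds 1 for cell "
                f"age={AGES[a]}, sex={SEXES[s]}, history={HISTORY_STATES[st]}"
            )
        trans = h.recurrent_mi + h.recurrent_stroke
        if (trans > 1).any():
            a, s, st = np.argwhere(trans > 1)[0]
            raise ParameterError(
                "recurrent event rates sum above 1 for cell "
                f"age={AGES[a]}, sex={SEXES[s]}, history={HISTORY_STATES[st]}"
            )


class EventLedger:
    """Annual totals of deaths and events; the unit of scenario comparison."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in LEDGER_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"ledger frame missing columns {missing}")
        self.frame = frame[list(LEDGER_COLUMNS)].copy()
        self.frame.index.name = "year"

    @classmethod
    def from_slices(cls, slices: Mapping[int, Mapping[str, float]]) -> "EventLedger":
        return cls(pd.DataFrame.from_dict(dict(slices), orient="index"))

    def totals(self) -> pd.Series:
        return self.frame.sum(axis=0)

    @property
    def years(self) -> list[int]:
        return list(self.frame.index)

    def equals(self, other: "EventLedger") -> bool:
        return self.frame.equals(other.frame)

    def to_tidy_csv(self, path: str | Path, scenario: str = "baseline") -> None:
        tidy = (
            self.frame.reset_index()
            .melt(id_vars="year", var_name="category", value_name="count")
            .assign(scenario=scenario)
        )[["year", "category", "scenario", "count"]]
        tidy.to_csv(path, index=False)

    @classmethod
    def from_tidy_csv(cls, path: str | Path) -> "EventLedger":
        tidy = pd.read_csv(path, comment="#")
        wide = tidy.pivot_table(index="year", columns="category", values="count")
        return cls(wide)


# --------------------------------------------------------------------------
# dynamics


def _competing_exits(probs: list[np.ndarray], n: np.ndarray) -> list[np.ndarray]:
    """Expected exit counts per cause under the product-of-survivals split.

    Total exits are n * (1 - prod(1 - p_k)); each cause receives a share
    proportional to its marginal probability.  With a single non-zero cause
    this reduces to n * p.
    """
    total_p = np.ones_like(n)
    psum = np.zeros_like(n)
    for p in probs:
        total_p = total_p * (1.0 - p)
        psum = psum + p
    total_exit = n * (1.0 - total_p)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = [np.where(psum > 0, p / np.where(psum > 0, psum, 1.0), 0.0) for p in probs]
    return [total_exit * s for s in shares]


def _first_event_probabilities(
    params: ModelParameters, delta_sbp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Annual first CHD / stroke probability per (age, sex, stratum) cell."""
    cov = params.covariates
    sbp = cov.sbp - delta_sbp
    if (sbp <= 0).any():
        raise ParameterError("SBP shift drives a cell's mean SBP non-positive")
    antihyp = np.zeros((N_AGE, N_SEX, N_STRATUM))
    antihyp[:, :, STRATA.index("hypertensive_treated")] = 1.0
    age_grid = np.broadcast_to(AGES[:, None], (N_AGE, N_SEX)).astype(float)

    def grid_prob(coeffs: RiskCoefficients, terms: dict[str, np.ndarray]) -> np.ndarray:
        lp = coeffs.term_grid(AGES, "intercept")[:, :, None]
        lp = np.broadcast_to(lp, (N_AGE, N_SEX, N_STRATUM)).copy()
        for term, x in terms.items():
            beta = coeffs.term_grid(AGES, term)[:, :, None]
            lp += beta * x
        return expit(lp)

    common = {
        "age": age_grid[:, :, None],
        "sbp": sbp,
        "smoker": cov.smoker[:, :, None],
        "diabetes": cov.diabetes[:, :, None],
    }
    chd_terms = dict(common)
    chd_terms.update(
        ldl=cov.ldl[:, :, None], hdl=cov.hdl[:, :, None], antihypertensive=antihyp
    )
    return grid_prob(params.chd_coeffs, chd_terms), grid_prob(params.stroke_coeffs, common)


def scenario_sbp_shift(
    params: ModelParameters,
    scenario: PolicyScenario | None,
    effect: SBPEffectModel,
    year: int,
) -> np.ndarray:
    """Per-cell SBP reduction (mmHg) in force during calendar ``year``.

    The cumulative intake reduction for the year is converted to grams of
    salt per sex and multiplied by the subgroup slope: the high slope for
    hypertensive strata or ages at/above the elderly threshold, the low
    slope otherwise.  Years before the scenario starts get no shift.
    """
    delta = np.zeros((N_AGE, N_SEX, N_STRATUM))
    if scenario is None or year < scenario.start_year:
        return delta
    frac = cumulative_reduction(scenario, year - scenario.start_year)
    slope = np.full((N_AGE, N_SEX, N_STRATUM), effect.slope_low)
    slope[:, :, 1:] = effect.slope_high  # hypertensive strata
    slope[AGES >= effect.elderly_age_threshold, :, :] = effect.slope_high
    for j, sex in enumerate(SEXES):
        salt_g = sodium_to_salt(sodium_reduction(params.intake_mg_day[sex], frac))
        delta[:, j, :] = salt_g * slope[:, j, :]
    return delta


def step_year(
    state: PopulationState,
    params: ModelParameters,
    delta_sbp: np.ndarray | None = None,
) -> tuple[PopulationState, dict[str, float]]:
    """Advance the population one calendar year.

    Returns the next year's state and the ledger slice (deaths and events)
    for the year just simulated.  ``delta_sbp`` is the per-cell SBP shift
    from the policy scenario; ``None`` means no intervention.
    """
    params.validate()
    if delta_sbp is None:
        delta_sbp = np.zeros((N_AGE, N_SEX, N_STRATUM))
    counts = state.counts
    healthy = counts[:, :, :, 0]

    # --- demographic-epidemiological submodel: first events, non-CVD deaths
    p_chd, p_stroke = _first_event_probabilities(params, delta_sbp)
    p_nc = np.broadcast_to(params.demography.noncvd_mortality[:, :, None], healthy.shape)
    chd_events, stroke_events, healthy_nc_deaths = _competing_exits(
        [p_chd, p_stroke, np.asarray(p_nc)], healthy
    )

    # --- bridge submodel: 30-day case fatality of the first event
    b = params.bridge
    cf1_c = b.cf1_chd[:, :, None]
    cf28_c = b.cf28_chd[:, :, None]
    chd_day1 = chd_events * cf1_c
    chd_day28 = chd_events * (1 - cf1_c) * cf28_c
    chd_surv = chd_events * (1 - cf1_c) * (1 - cf28_c)

    cf1_s = b.cf1_stroke[:, :, None]
    cf28_s = b.cf28_stroke[:, :, None]
    str_day1 = stroke_events * cf1_s
    str_day28 = stroke_events * (1 - cf1_s) * cf28_s
    str_surv = stroke_events * (1 - cf1_s) * (1 - cf28_s)

    # --- disease-history submodel
    hist = counts[:, :, :, 1:]  # (age, sex, stratum, 3)
    h = params.history
    p_cvd_d = np.broadcast_to(h.cvd_death[:, :, None, :], hist.shape)
    p_nc_d = np.broadcast_to(h.noncvd_death[:, :, None, :], hist.shape)
    hist_cvd_deaths, hist_nc_deaths = _competing_exits(
        [np.asarray(p_cvd_d), np.asarray(p_nc_d)], hist
    )
    hist_surv = hist - hist_cvd_deaths - hist_nc_deaths
    rec_mi = hist_surv * np.broadcast_to(h.recurrent_mi[:, :, None, :], hist.shape)
    rec_stroke = hist_surv * np.broadcast_to(h.recurrent_stroke[:, :, None, :], hist.shape)

    # state transitions among history survivors: a recurrent stroke moves a
    # post-MI survivor to post-both; a recurrent MI moves a post-stroke
    # survivor to post-both; post-both absorbs.
    i_mi, i_st, i_bo = 0, 1, 2
    new_hist = hist_surv.copy()
    move_mi_to_both = rec_stroke[:, :, :, i_mi]
    move_st_to_both = rec_mi[:, :, :, i_st]
    new_hist[:, :, :, i_mi] -= move_mi_to_both
    new_hist[:, :, :, i_st] -= move_st_to_both
    new_hist[:, :, :, i_bo] += move_mi_to_both + move_st_to_both

    # bridge survivors join the matching history state this cycle
    new_hist[:, :, :, i_mi] += chd_surv
    new_hist[:, :, :, i_st] += str_surv

    new_healthy = healthy - chd_events - stroke_events - healthy_nc_deaths

    next_counts = np.empty_like(counts)
    next_counts[:, :, :, 0] = new_healthy
    next_counts[:, :, :, 1:] = new_hist

    # --- ledger slice -----------------------------------------------------
    hist_cvd_chd = (
        hist_cvd_deaths[:, :, :, i_mi].sum() + 0.5 * hist_cvd_deaths[:, :, :, i_bo].sum()
    )
    hist_cvd_str = (
        hist_cvd_deaths[:, :, :, i_st].sum() + 0.5 * hist_cvd_deaths[:, :, :, i_bo].sum()
    )
    chd_deaths = float(chd_day1.sum() + chd_day28.sum() + hist_cvd_chd)
    stroke_deaths = float(str_day1.sum() + str_day28.sum() + hist_cvd_str)
    other_deaths = float(healthy_nc_deaths.sum() + hist_nc_deaths.sum())
    mi_events = float(b.mi_fraction_of_chd * chd_events.sum() + rec_mi.sum())
    angina_events = float((1 - b.mi_fraction_of_chd) * chd_events.sum())
    stroke_event_count = float(stroke_events.sum() + rec_stroke.sum())
    slice_ = {
        "total_deaths": chd_deaths + stroke_deaths + other_deaths,
        "chd_deaths": chd_deaths,
        "stroke_deaths": stroke_deaths,
        "other_deaths": other_deaths,
        "mi_events": mi_events,
        "stroke_events": stroke_event_count,
        "angina_events": angina_events,
    }

    # --- ageing and cohort entry ------------------------------------------
    aged = np.zeros_like(next_counts)
    aged[1:] = next_counts[:-1]
    aged_out_now = float(next_counts[-1].sum())
    incoming = params.demography.incoming_for(state.year)
    for j in range(N_SEX):
        aged[0, j, :, 0] = incoming[j] * params.demography.incoming_stratum_split
    aged = np.clip(aged, 0.0, None)  # guard against -0.0 / rounding dust

    next_state = PopulationState(
        year=state.year + 1,
        counts=aged,
        dead_chd=state.dead_chd + chd_deaths,
        dead_stroke=state.dead_stroke + stroke_deaths,
        dead_other=state.dead_other + other_deaths,
        aged_out=state.aged_out + aged_out_now,
    )
    return next_state, slice_


def run_projection(
    initial: PopulationState,
    params: ModelParameters,
    scenario: PolicyScenario | None = None,
    effect: SBPEffectModel | None = None,
    start: int | None = None,
    end: int = 2023,
) -> EventLedger:
    """Project the cohort from ``start`` (default: the state's year) to ``end``.

    One cycle is simulated per calendar year in ``[start, end)``, so the
    default 2013-2023 window comprises ten annual cycles.  ``scenario=None``
    produces the baseline ledger.
    """
    if effect is None:
        effect = SBPEffectModel()
    if start is None:
        start = initial.year
    if end <= start:
        raise ValueError("projection horizon must be at least one year")
    state = initial.copy()
    state.year = start
    slices: dict[int, dict[str, float]] = {}
    for year in range(start, end):
        delta = scenario_sbp_shift(params, scenario, effect, year)
        state, slices[year] = step_year(state, params, delta)
    return EventLedger.from_slices(slices)


def avoided_events(baseline: EventLedger, intervention: EventLedger) -> pd.DataFrame:
    """Per-category avoided events and percent reductions over the horizon.

    avoided = baseline total - intervention total; percent reduction =
    avoided / baseline * 100 (0 where the baseline category is empty).
    """
    if baseline.years != intervention.years:
        raise ValueError("ledgers cover different horizons")
    b = baseline.totals()
    i = intervention.totals()
    avoided = b - i
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(b > 0, avoided / b * 100.0, 0.0)
    return pd.DataFrame(
        {"baseline": b, "intervention": i, "avoided": avoided, "percent_reduction": pct}
    )
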