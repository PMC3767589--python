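"""State-transition engine: bookkeeping identities, the bridge cascade and
scenario comparisons."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from saltshift.intervention import PolicyScenario, SBPEffectModel
from saltshift.model import (
    AGES,
    N_AGE,
    N_SEX,
    N_STRATUM,
    N_STATE,
    STATES,
    BridgeParameters,
    CovariateGrid,
    DemographyInputs,
    DiseaseHistoryParameters,
    EventLedger,
    ModelParameters,
    ParameterError,
    PopulationState,
    avoided_events,
    run_projection,
    step_year,
)
from saltshift.risk import AGE_BANDS, RiskCoefficients, band_label
from saltshift.synthetic import GeneratorConfig, generate_model_inputs

LEDGER_CATEGORIES = [
    "total_deaths", "chd_deaths", "stroke_deaths", "mi_events", "stroke_events",
    "angina_events",
]


def flat_coeffs(outcome, p):
    """Coefficients giving every cell the same annual probability ``p``."""
    intercept = float(logit(p)) if p > 0 else -np.inf
    table = {
        (sex, band_label(band)): {"intercept": intercept}
        for sex in ("male", "female")
        for band in AGE_BANDS
    }
    return RiskCoefficients(outcome=outcome, table=table)


def single_cell_setup(
    n=1000.0, p_chd=0.1, cf1=0.3, cf28=0.1, age=55, mi_fraction=1.0
):
    """A population of ``n`` healthy persons in one cell, CHD risk only."""
    counts = np.zeros((N_AGE, N_SEX, N_STRATUM, N_STATE))
    counts[age - 35, 0, 0, 0] = n
    state = PopulationState(year=2013, counts=counts)
    ones = np.ones((N_AGE, N_SEX))
    shape3 = (N_AGE, N_SEX, 3)
    params = ModelParameters(
        covariates=CovariateGrid(
            sbp=np.full((N_AGE, N_SEX, N_STRATUM), 130.0),
            smoker=ones * 0.0, ldl=ones * 120.0, hdl=ones * 45.0, diabetes=ones * 0.0,
        ),
        chd_coeffs=flat_coeffs("chd", p_chd),
        stroke_coeffs=flat_coeffs("stroke", 0.0),
        bridge=BridgeParameters(
            cf1_chd=ones * cf1, cf28_chd=ones * cf28,
            cf1_stroke=ones * 0.0, cf28_stroke=ones * 0.0,
            mi_fraction_of_chd=mi_fraction,
        ),
        history=DiseaseHistoryParameters(
            recurrent_mi=np.zeros(shape3), recurrent_stroke=np.zeros(shape3),
            cvd_death=np.zeros(shape3), noncvd_death=np.zeros(shape3),
        ),
        demography=DemographyInputs(
            noncvd_mortality=np.zeros((N_AGE, N_SEX)), incoming_35={}
        ),
        intake_mg_day={"male": 4832.0, "female": 3983.0},
    )
    return state, params


class TestBridgeCascade:
    def test_worked_example_100_30_7_63(self):
        """1000 healthy, event probability 0.1, 1-day CF 0.3, 28-day CF 0.1:
        100 events, 30 day-1 deaths, 7 late deaths, 63 into the history state."""
        state, params = single_cell_setup()
        nxt, sl = step_year(state, params)
        assert sl["mi_events"] == pytest.approx(100.0)
        assert sl["chd_deaths"] == pytest.approx(30.0 + 7.0)
        assert sl["total_deaths"] == pytest.approx(37.0)
        # survivors are one year older and in the post-MI state
        assert nxt.counts[55 - 35 + 1, 0, 0, STATES.index("post_mi")] == pytest.approx(63.0)
        assert nxt.counts[55 - 35 + 1, 0, 0, 0] == pytest.approx(900.0)

    def test_total_case_fatality_leaves_history_empty(self):
        state, params = single_cell_setup(cf1=1.0, cf28=0.0)
        nxt, sl = step_year(state, params)
        assert sl["chd_deaths"] == pytest.approx(100.0)
        assert nxt.counts[:, :, :, 1:].sum() == 0.0

    def test_angina_excluded_from_mi_column(self):
        state, params = single_cell_setup(mi_fraction=0.6)
        _, sl = step_year(state, params)
        assert sl["mi_events"] == pytest.approx(60.0)
        assert sl["angina_events"] == pytest.approx(40.0)


class TestConservation:
    def test_identity_every_cycle(self, desk):
        initial, params = desk
        state = initial.copy()
        for year in range(2013, 2023):
            before = state.total_persons
            incoming = params.demography.incoming_for(state.year).sum()
            prev_dead = state.dead_chd + state.dead_stroke + state.dead_other
            prev_aged = state.aged_out
            state, sl = step_year(state, params)
            deaths = (state.dead_chd + state.dead_stroke + state.dead_other) - prev_dead
            aged = state.aged_out - prev_aged
            lhs = state.total_persons + deaths + aged
            rhs = before + incoming
            assert lhs == pytest.approx(rhs, rel=1e-12)
            assert deaths == pytest.approx(sl["total_deaths"], rel=1e-12)

    def test_cvd_deaths_bounded_by_total(self, desk):
        initial, params = desk
        ledger = run_projection(initial, params, end=2023)
        assert (
            ledger.frame["chd_deaths"] + ledger.frame["stroke_deaths"]
            <= ledger.frame["total_deaths"] + 1e-9
        ).all()

    def test_null_dynamics_is_pure_ageing(self):
        initial, params = generate_model_inputs(GeneratorConfig(seed=3, rate_scale=0.0))
        nxt, sl = step_year(initial, params)
        assert all(v == 0.0 for v in sl.values())
        expected = np.zeros_like(initial.counts)
        expected[1:] = initial.counts[:-1]
        incoming = params.demography.incoming_for(initial.year)
        for j in range(N_SEX):
            expected[0, j, :, 0] = incoming[j] * params.demography.incoming_stratum_split
        np.testing.assert_allclose(nxt.counts, expected, rtol=1e-12)


class TestProjection:
    def test_null_scenario_ledger_identical_to_baseline(self, desk):
        initial, params = desk
        baseline = run_projection(initial, params, end=2023)
        null = run_projection(
            initial, params,
            PolicyScenario(name="null", annual_reduction_fractions=()),
            SBPEffectModel(), end=2023,
        )
        assert null.equals(baseline)

    def test_scenarios_agree_while_schedules_agree(self, desk, scenarios):
        initial, params = desk
        s1, s2, effect = scenarios
        l1 = run_projection(initial, params, s1, effect, end=2023)
        l2 = run_projection(initial, params, s2, effect, end=2023)
        # identical 4%+4% schedules through the second projection year
        pd.testing.assert_frame_equal(l1.frame.loc[2013:2014], l2.frame.loc[2013:2014])
        assert not l1.frame.loc[2015:].equals(l2.frame.loc[2015:])

    def test_ten_year_totals_equal_sum_of_slices(self, desk):
        initial, params = desk
        ledger = run_projection(initial, params, end=2023)
        assert len(ledger.years) == 10
        np.testing.assert_allclose(
            ledger.totals().to_numpy(), ledger.frame.sum(axis=0).to_numpy()
        )

    def test_intervention_never_increases_events_or_cvd_deaths(self, desk, scenarios):
        initial, params = desk
        s1, s2, effect = scenarios
        baseline = run_projection(initial, params, end=2023)
        for scen in (s1, s2):
            av = avoided_events(baseline, run_projection(initial, params, scen, effect, end=2023))
            assert (av.loc[LEDGER_CATEGORIES, "avoided"] >= 0).all()

    def test_sustained_scenario_dominates_two_year_scenario(self, desk, scenarios):
        initial, params = desk
        s1, s2, effect = scenarios
        baseline = run_projection(initial, params, end=2023)
        av1 = avoided_events(baseline, run_projection(initial, params, s1, effect, end=2023))
        av2 = avoided_events(baseline, run_projection(initial, params, s2, effect, end=2023))
        assert (
            av2.loc[LEDGER_CATEGORIES, "avoided"] >= av1.loc[LEDGER_CATEGORIES, "avoided"]
        ).all()

    def test_projection_is_deterministic(self, desk):
        initial, params = desk
        a = run_projection(initial, params, end=2023)
        b = run_projection(initial, params, end=2023)
        assert a.equals(b)

    def test_degenerate_horizon_rejected(self, desk):
        initial, params = desk
        with pytest.raises(ValueError):
            run_projection(initial, params, start=2020, end=2020)


class TestAvoidedEvents:
    def test_identical_ledgers_are_all_zero(self, desk):
        initial, params = desk
        ledger = run_projection(initial, params, end=2023)
        av = avoided_events(ledger, ledger)
        assert (av["avoided"] == 0).all()
        assert (av["percent_reduction"] == 0).all()

    def test_printed_pair_consistency(self):
        """Avoided/baseline ratios match the published percent reductions."""
        base = EventLedger.from_slices(
            {2013: {"total_deaths": 3_100_000, "chd_deaths": 593_000, "stroke_deaths": 0,
                    "other_deaths": 0, "mi_events": 864_000, "stroke_events": 1_010_000,
                    "angina_events": 0}}
        )
        interv = EventLedger.from_slices(
            {2013: {"total_deaths": 3_100_000 - 19_000, "chd_deaths": 593_000 - 6_000,
                    "stroke_deaths": 0, "other_deaths": 0, "mi_events": 864_000 - 13_000,
                    "stroke_events": 1_010_000 - 10_000, "angina_events": 0}}
        )
        av = avoided_events(base, interv)
        assert round(av.loc["total_deaths", "percent_reduction"], 1) == 0.6
        assert round(av.loc["mi_events", "percent_reduction"], 1) == 1.5
        assert round(av.loc["stroke_events", "percent_reduction"], 1) == 1.0

    def test_mismatched_horizons_rejected(self, desk):
        initial, params = desk
        a = run_projection(initial, params, end=2023)
        b = run_projection(initial, params, end=2020)
        with pytest.raises(ValueError):
            avoided_events(a, b)


class TestParameterValidation:
    def test_excess_exit_probability_names_the_cell(self):
        state, params = single_cell_setup()
        params.history.cvd_death[40 - 35, 1, 2] = 1.5
        with pytest.raises(ParameterError, match="age=40.*female.*post_both"):
            step_year(state, params)

    def test_excess_recurrence_rejected(self):
        state, params = single_cell_setup()
        params.history.recurrent_mi[:, :, 0] = 0.6
        params.history.recurrent_stroke[:, :, 0] = 0.6
        with pytest.raises(ParameterError, match="recurrent"):
            step_year(state, params)


def test_ledger_tidy_csv_round_trip(tmp_path, desk):
    initial, params = desk
    ledger = run_projection(initial, params, end=2023)
    path = tmp_path / "ledger.csv"
    ledger.to_tidy_csv(path, scenario="baseline")
    loaded = EventLedger.from_tidy_csv(path)
    pd.testing.assert_frame_equal(
        loaded.frame, ledger.frame, check_names=False, check_column_type=False
    )
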