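"""Logistic risk engine: closed forms, recalibration algebra, validation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltshift.model import AGES, SEXES, STRATA
from saltshift.risk import (
    AGE_BANDS,
    RiskCoefficients,
    RiskProfile,
    annual_event_probability,
    band_label,
    rescale_alpha,
    shift_sbp,
)


def flat_coeffs(outcome="chd", intercept=0.0, **betas) -> RiskCoefficients:
    """Same terms in every sex/age-band cell."""
    cell = {"intercept": intercept, **betas}
    table = {
        (sex, band_label(band)): dict(cell) for sex in ("male", "female") for band in AGE_BANDS
    }
    return RiskCoefficients(outcome=outcome, table=table)


def profile(**overrides) -> RiskProfile:
    base = dict(
        age=55.0, sex="male", sbp=135.0, smoker=0.3, ldl=130.0, hdl=45.0,
        diabetes=0.08, antihypertensive=0.2,
    )
    base.update(overrides)
    return RiskProfile(**base)


class TestAnnualEventProbability:
    def test_logistic_at_zero(self):
        assert annual_event_probability(profile(), flat_coeffs()) == pytest.approx(0.5)

    def test_closed_form_intercept(self):
        coeffs = flat_coeffs(intercept=-math.log(99.0))
        assert annual_event_probability(profile(), coeffs) == pytest.approx(0.01)

    def test_matches_hand_evaluated_linear_predictor(self):
        coeffs = flat_coeffs(
            intercept=-9.0, age=0.05, sbp=0.018, smoker=0.5, ldl=0.006, hdl=-0.02,
            diabetes=0.6, antihypertensive=0.15,
        )
        p = profile()
        lp = (
            -9.0 + 0.05 * 55 + 0.018 * 135 + 0.5 * 0.3 + 0.006 * 130
            - 0.02 * 45 + 0.6 * 0.08 + 0.15 * 0.2
        )
        expected = 1.0 / (1.0 + math.exp(-lp))
        assert annual_event_probability(p, coeffs) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_signed_covariates(self):
        coeffs = flat_coeffs(intercept=-6.0, sbp=0.02, hdl=-0.02)
        base = annual_event_probability(profile(), coeffs)
        assert annual_event_probability(profile(sbp=150.0), coeffs) > base
        assert annual_event_probability(profile(hdl=60.0), coeffs) < base

    def test_missing_age_band_is_configuration_error(self):
        table = {
            (sex, band_label(band)): {"intercept": -5.0}
            for sex in ("male", "female")
            for band in AGE_BANDS[:-1]
        }
        with pytest.raises(ValueError, match="span 35-84"):
            RiskCoefficients(outcome="chd", table=table, age_bands=AGE_BANDS[:-1])

    def test_desk_fixture_probabilities_in_sanity_band(self, desk):
        _, params = desk
        for coeffs in (params.chd_coeffs, params.stroke_coeffs):
            for sex in SEXES:
                for age in (35.0, 50.0, 65.0, 84.0):
                    p = annual_event_probability(
                        profile(age=age, sex=sex, antihypertensive=0.0), coeffs
                    )
                    assert 1e-6 < p < 0.5


class TestShiftSBP:
    def test_zero_delta_identity(self):
        p = profile()
        assert shift_sbp(p, 0.0) == p

    def test_arithmetic(self):
        assert shift_sbp(profile(sbp=140.0), 1.81).sbp == pytest.approx(138.19)

    def test_probability_strictly_decreases_with_positive_sbp_beta(self):
        coeffs = flat_coeffs(intercept=-6.0, sbp=0.02)
        p = profile()
        assert annual_event_probability(shift_sbp(p, 1.81), coeffs) < annual_event_probability(
            p, coeffs
        )

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            shift_sbp(profile(), -1.0)
        with pytest.raises(ValueError):
            shift_sbp(profile(sbp=5.0), 5.0)


class TestRescaleAlpha:
    def test_identity_factor(self):
        coeffs = flat_coeffs(intercept=-3.0, sbp=0.02)
        assert rescale_alpha(coeffs, 1.0).table == coeffs.table

    def test_doubled_odds_from_even(self):
        coeffs = flat_coeffs()
        p = annual_event_probability(profile(), rescale_alpha(coeffs, 2.0))
        assert p == pytest.approx(2.0 / 3.0)

    @given(a=st.floats(min_value=0.1, max_value=10), b=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_composition(self, a, b):
        coeffs = flat_coeffs(intercept=-4.0, sbp=0.02)
        double = rescale_alpha(rescale_alpha(coeffs, a), b)
        single = rescale_alpha(coeffs, a * b)
        for key in coeffs.table:
            assert double.table[key]["intercept"] == pytest.approx(
                single.table[key]["intercept"], rel=1e-12
            )

    def test_small_p_scales_linearly(self):
        coeffs = flat_coeffs(intercept=math.log(0.001 / 0.999))
        p0 = annual_event_probability(profile(), coeffs)
        p3 = annual_event_probability(profile(), rescale_alpha(coeffs, 3.0))
        assert p3 / p0 == pytest.approx(3.0, rel=5e-3)

    def test_betas_never_change(self):
        coeffs = flat_coeffs(intercept=-4.0, sbp=0.02, smoker=0.5)
        scaled = rescale_alpha(coeffs, 7.3)
        for key in coeffs.table:
            before = {t: v for t, v in coeffs.table[key].items() if t != "intercept"}
            after = {t: v for t, v in scaled.table[key].items() if t != "intercept"}
            assert before == after

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            rescale_alpha(flat_coeffs(), 0.0)


class TestCoefficientIO:
    def test_csv_round_trip(self, tmp_path, desk):
        _, params = desk
        path = tmp_path / "coeffs.csv"
        params.chd_coeffs.to_frame().to_csv(path, index=False)
        loaded = RiskCoefficients.from_csv(path, "chd")
        for key, terms in params.chd_coeffs.table.items():
            for t, v in terms.items():
                assert loaded.table[key][t] == pytest.approx(v, rel=1e-12)

    def test_stroke_covariate_set_enforced(self):
        with pytest.raises(ValueError, match="unexpected terms"):
            flat_coeffs(outcome="stroke", ldl=0.006)

    def test_chd_covariate_set_enforced(self):
        with pytest.raises(ValueError, match="unexpected terms"):
            flat_coeffs(outcome="chd", bmi=0.1)

    def test_intercept_required(self):
        table = {
            (sex, band_label(band)): {"sbp": 0.02}
            for sex in ("male", "female")
            for band in AGE_BANDS
        }
        with pytest.raises(ValueError, match="intercept"):
            RiskCoefficients(outcome="chd", table=table)


def test_profile_invariants():
    with pytest.raises(ValueError):
        profile(age=30.0)
    with pytest.raises(ValueError):
        profile(smoker=1.2)
    with pytest.raises(ValueError):
        profile(hdl=0.0)
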