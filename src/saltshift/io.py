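"""On-disk parameter-bundle dialect: one YAML index referencing CSV tables.

A bundle directory contains ``bundle.yaml`` plus plain CSV tables for the
covariate means, risk coefficients, case fatalities, disease-history rates,
non-CVD mortality, incoming cohorts and the baseline cell populations.
Written files carry '#' provenance header comments, which every reader
skips.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    AGES,
    HISTORY_STATES,
    N_AGE,
    N_SEX,
    N_STRATUM,
    N_STATE,
    SEXES,
    STATES,
    STRATA,
    BridgeParameters,
    CovariateGrid,
    DemographyInputs,
    DiseaseHistoryParameters,
    ModelParameters,
    PopulationState,
)
from .risk import RiskCoefficients

__all__ = ["write_bundle", "read_bundle"]

_TABLES = {
    "covariates": "covariates.csv",
    "coefficients": "coefficients.csv",
    "bridge": "bridge.csv",
    "disease_history": "disease_history.csv",
    "noncvd_mortality": "noncvd_mortality.csv",
    "incoming_cohorts": "incoming_cohorts.csv",
    "population": "population.csv",
}


def _write_csv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        for line in comment.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_bundle(
    directory: str | Path,
    initial: PopulationState,
    params: ModelParameters,
    provenance: str = "",
) -> Path:
    """Serialise a parameter bundle and initial population to a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    comment = provenance or "saltshift parameter bundle"

    cov = params.covariates
    rows = []
    for i, age in enumerate(AGES):
        for j, sex in enumerate(SEXES):
            for k, stratum in enumerate(STRATA):
                rows.append(
                    {
                        "age": int(age), "sex": sex, "stratum": stratum,
                        "sbp": cov.sbp[i, j, k], "smoker": cov.smoker[i, j],
                        "ldl": cov.ldl[i, j], "hdl": cov.hdl[i, j],
                        "diabetes": cov.diabetes[i, j],
                    }
                )
    _write_csv(pd.DataFrame(rows), d / _TABLES["covariates"], comment)

    coeffs = pd.concat(
        [params.chd_coeffs.to_frame(), params.stroke_coeffs.to_frame()], ignore_index=True
    )
    _write_csv(coeffs, d / _TABLES["coefficients"], comment)

    b = params.bridge
    rows = []
    for event, cf1, cf28 in (
        ("chd", b.cf1_chd, b.cf28_chd),
        ("stroke", b.cf1_stroke, b.cf28_stroke),
    ):
        for i, age in enumerate(AGES):
            for j, sex in enumerate(SEXES):
                rows.append(
                    {"event": event, "age": int(age), "sex": sex,
                     "one_day_case_fatality": cf1[i, j],
                     "twentyeight_day_case_fatality": cf28[i, j]}
                )
    _write_csv(pd.DataFrame(rows), d / _TABLES["bridge"], comment)

    h = params.history
    rows = []
    for st_i, hstate in enumerate(HISTORY_STATES):
        for i, age in enumerate(AGES):
            for j, sex in enumerate(SEXES):
                rows.append(
                    {"history_state": hstate, "age": int(age), "sex": sex,
                     "recurrent_mi": h.recurrent_mi[i, j, st_i],
                     "recurrent_stroke": h.recurrent_stroke[i, j, st_i],
                     "cvd_death": h.cvd_death[i, j, st_i],
                     "noncvd_death": h.noncvd_death[i, j, st_i]}
                )
    _write_csv(pd.DataFrame(rows), d / _TABLES["disease_history"], comment)

    dem = params.demography
    rows = [
        {"age": int(age), "sex": sex, "rate": dem.noncvd_mortality[i, j]}
        for i, age in enumerate(AGES)
        for j, sex in enumerate(SEXES)
    ]
    _write_csv(pd.DataFrame(rows), d / _TABLES["noncvd_mortality"], comment)

    rows = [
        {"year": year, "sex": sex, "count": counts[j]}
        for year, counts in sorted(dem.incoming_35.items())
        for j, sex in enumerate(SEXES)
    ]
    _write_csv(pd.DataFrame(rows), d / _TABLES["incoming_cohorts"], comment)

    rows = []
    for i, age in enumerate(AGES):
        for j, sex in enumerate(SEXES):
            for k, stratum in enumerate(STRATA):
                for m, dstate in enumerate(STATES):
                    rows.append(
                        {"age": int(age), "sex": sex, "stratum": stratum,
                         "state": dstate, "count": initial.counts[i, j, k, m]}
                    )
    _write_csv(pd.DataFrame(rows), d / _TABLES["population"], comment)

    index = {
        "tables": dict(_TABLES),
        "initial_year": int(initial.year),
        "intake_mg_day": {k: float(v) for k, v in params.intake_mg_day.items()},
        "mi_fraction_of_chd": float(b.mi_fraction_of_chd),
        "incoming_stratum_split": [float(x) for x in dem.incoming_stratum_split],
    }
    (d / "bundle.yaml").write_text(yaml.safe_dump(index, sort_keys=False))
    return d


def read_bundle(directory: str | Path) -> tuple[PopulationState, ModelParameters]:
    """Load a parameter bundle written by :func:`write_bundle`."""
    d = Path(directory)
    index = yaml.safe_load((d / "bundle.yaml").read_text())
    tables = index["tables"]

    def load(name: str) -> pd.DataFrame:
        return pd.read_csv(d / tables[name], comment="#")

    sex_idx = {s: j for j, s in enumerate(SEXES)}
    stratum_idx = {s: k for k, s in enumerate(STRATA)}
    state_idx = {s: m for m, s in enumerate(STATES)}
    hstate_idx = {s: m for m, s in enumerate(HISTORY_STATES)}
    age_idx = {int(a): i for i, a in enumerate(AGES)}

    cov_df = load("covariates")
    sbp = np.zeros((N_AGE, N_SEX, N_STRATUM))
    smoker = np.zeros((N_AGE, N_SEX))
    ldl = np.zeros((N_AGE, N_SEX))
    hdl = np.zeros((N_AGE, N_SEX))
    diabetes = np.zeros((N_AGE, N_SEX))
    for r in cov_df.itertuples(index=False):
        i, j, k = age_idx[int(r.age)], sex_idx[r.sex], stratum_idx[r.stratum]
        sbp[i, j, k] = r.sbp
        smoker[i, j], ldl[i, j], hdl[i, j], diabetes[i, j] = r.smoker, r.ldl, r.hdl, r.diabetes
    covariates = CovariateGrid(sbp=sbp, smoker=smoker, ldl=ldl, hdl=hdl, diabetes=diabetes)

    coeff_df = load("coefficients")
    chd = RiskCoefficients.from_frame(coeff_df, "chd")
    stroke = RiskCoefficients.from_frame(coeff_df, "stroke")

    bridge_df = load("bridge")
    grids = {e: (np.zeros((N_AGE, N_SEX)), np.zeros((N_AGE, N_SEX))) for e in ("chd", "stroke")}
    for r in bridge_df.itertuples(index=False):
        i, j = age_idx[int(r.age)], sex_idx[r.sex]
        grids[r.event][0][i, j] = r.one_day_case_fatality
        grids[r.event][1][i, j] = r.twentyeight_day_case_fatality
    bridge = BridgeParameters(
        cf1_chd=grids["chd"][0], cf28_chd=grids["chd"][1],
        cf1_stroke=grids["stroke"][0], cf28_stroke=grids["stroke"][1],
        mi_fraction_of_chd=float(index["mi_fraction_of_chd"]),
    )

    hist_df = load("disease_history")
    shape = (N_AGE, N_SEX, len(HISTORY_STATES))
    rec_mi, rec_st = np.zeros(shape), np.zeros(shape)
    cvd_d, nc_d = np.zeros(shape), np.zeros(shape)
    for r in hist_df.itertuples(index=False):
        i, j, m = age_idx[int(r.age)], sex_idx[r.sex], hstate_idx[r.history_state]
        rec_mi[i, j, m], rec_st[i, j, m] = r.recurrent_mi, r.recurrent_stroke
        cvd_d[i, j, m], nc_d[i, j, m] = r.cvd_death, r.noncvd_death
    history = DiseaseHistoryParameters(
        recurrent_mi=rec_mi, recurrent_stroke=rec_st, cvd_death=cvd_d, noncvd_death=nc_d
    )

    mort_df = load("noncvd_mortality")
    noncvd = np.zeros((N_AGE, N_SEX))
    for r in mort_df.itertuples(index=False):
        noncvd[age_idx[int(r.age)], sex_idx[r.sex]] = r.rate

    inc_df = load("incoming_cohorts")
    incoming: dict[int, np.ndarray] = {}
    for r in inc_df.itertuples(index=False):
        incoming.setdefault(int(r.year), np.zeros(N_SEX))[sex_idx[r.sex]] = r.count
    demography = DemographyInputs(
        noncvd_mortality=noncvd,
        incoming_35=incoming,
        incoming_stratum_split=np.asarray(index["incoming_stratum_split"], dtype=float),
    )

    pop_df = load("population")
    counts = np.zeros((N_AGE, N_SEX, N_STRATUM, N_STATE))
    for r in pop_df.itertuples(index=False):
        counts[age_idx[int(r.age)], sex_idx[r.sex], stratum_idx[r.stratum], state_idx[r.state]] = r.count
    initial = PopulationState(year=int(index["initial_year"]), counts=counts)

    params = ModelParameters(
        covariates=covariates,
        chd_coeffs=chd,
        stroke_coeffs=stroke,
        bridge=bridge,
        history=history,
        demography=demography,
        intake_mg_day={k: float(v) for k, v in index["intake_mg_day"].items()},
    )
    params.validate()
    return initial, params
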