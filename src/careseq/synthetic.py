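"""Synthetic claims-table generator with a planted two-archetype structure.

Real statutory-insurer claims for this population are access-restricted, so
every downstream stage of the pipeline is exercised on simulated tables that
emulate the study's statistical structure: a ~75/25 mixture of a
guideline-adherent and a care-with-gaps archetype, archetype membership
following a logistic model of parental-SES covariates, conditionally
independent per-quarter/per-year care events given the archetype, and
Poisson hospitalization counts with archetype-specific means.

The ground-truth archetype is emitted in a separate ``truth`` table that the
analysis pipeline never reads; it exists only so simulations can score
cluster recovery.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import GeneratorConfig, SES_FIELDS

TABLE_NAMES = ("patients", "diagnoses", "events", "hospitalizations", "truth")

_QUARTER_STARTS = {1: (1, 1), 2: (4, 1), 3: (7, 1), 4: (10, 1)}


def _quarter_start_dates(window: tuple[date, date]) -> list[date]:
    """Chronological list of quarter-start dates covering the window."""
    starts = []
    y, q = window[0].year, (window[0].month - 1) // 3 + 1
    while True:
        m, d = _QUARTER_STARTS[q]
        s = date(y, m, d)
        if s > window[1]:
            break
        starts.append(s)
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return starts


def _offset_iso(starts: np.ndarray, days: int) -> np.ndarray:
    """ISO date strings ``starts + days`` for an array of date objects."""
    base = pd.to_datetime(pd.Series(starts)) + pd.Timedelta(days=days)
    return base.dt.strftime("%Y-%m-%d").to_numpy()


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean(expit(b0 + eta)) == target.

    Keeps the configured covariate log-odds untouched while pinning the
    marginal archetype mixture at the configured proportion.
    """
    if target >= 1.0:
        return np.inf

    def gap(b0):
        return float(expit(b0 + eta).mean()) - target

    return brentq(gap, -40.0, 40.0, xtol=1e-10)


def generate_patients(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the patient master table and its ground-truth archetype table.

    Covariates are drawn from the configured marginal prevalences; the
    latent archetype is then drawn from a logistic model whose slopes are
    ``config.ses_logit_coefficients`` and whose intercept is calibrated so
    the expected adherent share equals ``mixture_proportion_adherent``.
    SES missingness is applied after the archetype draw (missingness masks
    observation, it does not alter the data-generating covariates).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    prev = config.covariate_prevalence

    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    by_items = sorted(prev["birth_year"].items())
    by_vals = np.array([k for k, _ in by_items])
    by_p = np.array([v for _, v in by_items], dtype=float)
    birth_year = rng.choice(by_vals, size=n, p=by_p / by_p.sum())

    cols: dict[str, np.ndarray] = {"patient_id": patient_id, "birth_year": birth_year}
    for name in (
        "sex_female", "dmp_enrolled", "comorbidity_autoimmune",
        "comorbidity_asthma", "comorbidity_psychological",
        "comorbidity_cardiovascular", "education_abitur", "university_degree",
        "unemployed", "migration_history",
    ):
        cols[name] = rng.random(n) < prev[name]
    for name in ("job_type", "district_type"):
        items = list(prev[name].items())
        labels = np.array([k for k, _ in items])
        p = np.array([v for _, v in items], dtype=float)
        cols[name] = rng.choice(labels, size=n, p=p / p.sum())

    # latent archetype from the SES logistic model
    eta = np.zeros(n)
    for name, beta in config.ses_logit_coefficients.items():
        if name == "birth_year_centered":
            x = birth_year - birth_year.mean()
        else:
            x = cols[name].astype(float)
        eta = eta + beta * x
    b0 = _calibrate_intercept(eta, config.mixture_proportion_adherent)
    p_adherent = expit(b0 + eta) if np.isfinite(b0) else np.ones(n)
    adherent = rng.random(n) < p_adherent

    ses_missing = rng.random(n) < config.ses_missing_rate
    hosp_outpatient = rng.random(n) < config.hospital_outpatient_fraction

    patients = pd.DataFrame(cols)
    patients["sex"] = np.where(patients.pop("sex_female"), "female", "male")
    patients["district_type"] = cols["district_type"]
    span = f"{date(config.lookback_year, 1, 1).isoformat()}/{config.observation_window[1].isoformat()}"
    patients["coverage"] = span
    patients["ses_missing"] = ses_missing
    for f in SES_FIELDS:
        patients[f] = patients[f].astype(object)
        patients.loc[ses_missing, f] = pd.NA

    truth = pd.DataFrame(
        {
            "patient_id": patient_id,
            "archetype": np.where(adherent, "adherent", "gaps"),
            "hospital_outpatient": hosp_outpatient,
        }
    )
    return patients, truth


def _bernoulli_event_rows(
    patient_id, fired, starts, code, day_offset, setting="outpatient", quantity=None
) -> pd.DataFrame:
    """Long-format rows for a (patient x interval) Bernoulli event matrix."""
    pi, qi = np.nonzero(fired)
    df = pd.DataFrame(
        {
            "patient_id": patient_id[pi],
            "date": _offset_iso(np.asarray(starts, dtype=object)[qi], day_offset),
            "event_code": code,
            "quantity": quantity[pi, qi] if quantity is not None else np.nan,
            "setting": setting,
        }
    )
    return df


def generate_cohort(config: GeneratorConfig) -> dict[str, pd.DataFrame]:
    """Generate the four claims-like tables plus the ground-truth table.

    Returns a dict with keys ``patients``, ``diagnoses``, ``events``,
    ``hospitalizations`` and ``truth``. Identical config (including seed)
    yields identical tables.
    """
    rng = np.random.default_rng(config.seed)
    patients, truth = generate_patients(config, rng)
    n = config.n_patients
    pid = patients["patient_id"].to_numpy()
    adherent = (truth["archetype"] == "adherent").to_numpy()
    hosp_outpatient = truth["hospital_outpatient"].to_numpy()

    qstarts = _quarter_start_dates(config.observation_window)
    ystarts = [s for s in qstarts if s.month == 1]
    nq, ny = len(qstarts), len(ystarts)

    def rate(field: str) -> np.ndarray:
        a = getattr(config.rates_adherent, field)
        g = getattr(config.rates_gaps, field)
        return np.where(adherent, a, g)[:, None]

    frames = []
    # HCP contact dimension (quarterly)
    fired = rng.random((n, nq)) < rate("contact")
    frames.append(_bernoulli_event_rows(pid, fired, qstarts, "OUTPATIENT_CONTACT", 10))

    # diagnostics dimension (quarterly): HbA1c and test-strip prescriptions
    fired = rng.random((n, nq)) < rate("hba1c")
    frames.append(_bernoulli_event_rows(pid, fired, qstarts, "HBA1C", 20))

    strips_ok = rng.random((n, nq)) < rate("strips")
    qty = np.where(
        strips_ok,
        config.strips_threshold + 50 * rng.integers(0, 4, size=(n, nq)),
        rng.integers(50, config.strips_threshold, size=(n, nq)),
    ).astype(float)
    sub = (~strips_ok) & (rng.random((n, nq)) < config.strips_subthreshold_rate)
    frames.append(
        _bernoulli_event_rows(pid, strips_ok | sub, qstarts, "STRIPS_RX", 25, quantity=qty)
    )

    # screening dimension (annual)
    for code, field_, off in (
        ("RETINOPATHY_SCREEN", "retinopathy", 40),
        ("CHOLESTEROL_SCREEN", "cholesterol", 120),
        ("THYROID_SCREEN", "thyroid", 200),
    ):
        fired = rng.random((n, ny)) < rate(field_)
        frames.append(_bernoulli_event_rows(pid, fired, ystarts, code, off))

    # planted hospital outpatients: contacts in >= 8 distinct quarters billed
    # by a hospital outpatient center, to exercise the exclusion rule
    if hosp_outpatient.any():
        fired = np.zeros((n, nq), dtype=bool)
        fired[hosp_outpatient, : min(10, nq)] = True
        frames.append(
            _bernoulli_event_rows(
                pid, fired, qstarts, "OUTPATIENT_CONTACT", 12,
                setting="hospital_outpatient",
            )
        )

    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(
        ["patient_id", "date", "event_code"], kind="mergesort"
    ).reset_index(drop=True)

    # diagnosis confirmation pattern in the lookback year: 90% of patients
    # carry two outpatient diagnoses in distinct quarters, 10% one inpatient
    inpatient_path = rng.random(n) < 0.10
    lb_starts = _quarter_start_dates(
        (date(config.lookback_year, 1, 1), date(config.lookback_year, 12, 31))
    )
    q_pairs = np.array([rng.choice(4, size=2, replace=False) for _ in range(n)])
    diag_frames = []
    out_idx = np.nonzero(~inpatient_path)[0]
    for col in (0, 1):
        qi = q_pairs[out_idx, col]
        diag_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[out_idx],
                    "date": _offset_iso(np.asarray(lb_starts, dtype=object)[qi], 15),
                    "setting": "outpatient",
                    "code": "E10",
                }
            )
        )
    in_idx = np.nonzero(inpatient_path)[0]
    qi = q_pairs[in_idx, 0]
    diag_frames.append(
        pd.DataFrame(
            {
                "patient_id": pid[in_idx],
                "date": _offset_iso(np.asarray(lb_starts, dtype=object)[qi], 15),
                "setting": "inpatient",
                "code": "E10",
            }
        )
    )
    diagnoses = (
        pd.concat(diag_frames, ignore_index=True)
        .sort_values(["patient_id", "date"], kind="mergesort")
        .reset_index(drop=True)
    )

    # hospitalizations with T1DM as primary diagnosis: Poisson per 3 years
    lam = np.where(adherent, config.hosp_rate_adherent, config.hosp_rate_gaps)
    counts = rng.poisson(lam)
    hp = np.repeat(np.arange(n), counts)
    day = rng.integers(0, (config.observation_window[1] - config.observation_window[0]).days + 1,
                       size=hp.size)
    hosp_dates = (
        pd.to_datetime(config.observation_window[0]) + pd.to_timedelta(day, unit="D")
    ).strftime("%Y-%m-%d")
    hospitalizations = pd.DataFrame(
        {"patient_id": pid[hp], "date": hosp_dates, "primary_t1dm": True}
    )
    hospitalizations = hospitalizations.sort_values(
        ["patient_id", "date"], kind="mergesort"
    ).reset_index(drop=True)

    return {
        "patients": patients,
        "diagnoses": diagnoses,
        "events": events,
        "hospitalizations": hospitalizations,
        "truth": truth,
    }


def write_fixture(
    tables: Mapping[str, pd.DataFrame], directory, config: GeneratorConfig | None = None
) -> dict[str, Path]:
    """Write generated tables as CSV files plus a JSON config sidecar.

    ``truth.csv`` holds the generator-only archetype labels and is never an
    input of the analysis pipeline. Output is byte-deterministic for a fixed
    table set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLE_NAMES:
        if name not in tables:
            continue
        path = directory / f"{name}.csv"
        tables[name].to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    if config is not None:
        sidecar = directory / "generator_config.json"
        sidecar.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
        paths["config"] = sidecar
    return paths


_BOOL_COLS = {
    "patients": [
        "dmp_enrolled", "comorbidity_autoimmune", "comorbidity_asthma",
        "comorbidity_psychological", "comorbidity_cardiovascular", "ses_missing",
    ],
    "hospitalizations": ["primary_t1dm"],
    "truth": ["hospital_outpatient"],
}

# parental SES booleans may be missing, so they round-trip as nullable object
_NULLABLE_BOOL = ("education_abitur", "university_degree", "unemployed", "migration_history")


def read_fixture(directory) -> dict[str, pd.DataFrame]:
    """Read tables written by :func:`write_fixture` back into DataFrames."""
    directory = Path(directory)
    tables = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            if name == "truth":
                continue
            raise FileNotFoundError(f"missing input table: {path}")
        df = pd.read_csv(path, dtype={"patient_id": str})
        for col in _BOOL_COLS.get(name, []):
            if col in df:
                df[col] = df[col].astype(bool)
        if name == "patients":
            for col in _NULLABLE_BOOL:
                if col in df:
                    df[col] = df[col].map(
                        {True: True, False: False, "True": True, "False": False}
                    ).astype(object)
                    df.loc[df[col].isna(), col] = pd.NA
            if "job_type" in df:
                df["job_type"] = df["job_type"].astype(object)
                df.loc[df["job_type"].isna(), "job_type"] = pd.NA
        tables[name] = df
    return tables
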