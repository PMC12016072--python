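"""Analytic-cohort construction from claims-like tables.

Inclusion rules, applied in a fixed order for attrition reporting:

1. confirmed T1DM diagnosis in the lookback year — the diagnosis code
   appears in at least two distinct calendar quarters in the outpatient
   setting, or at least once in the inpatient setting;
2. birth year inside the configured window (default 2003-2006, i.e. aged
   11-14 in the first observation year);
3. continuous insurance coverage across the lookback + observation years;
4. NOT a hospital outpatient (treated at a hospital outpatient center in at
   least 8 of the 12 observation quarters — such care is billed as a
   quarterly lump sum, so individual procedures are untrackable).

The final flags are conjunctive, so the included set does not depend on
rule order; only the attrition attribution (first failing rule) does.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import pandas as pd

RULE_ORDER = ("confirmed_dx", "age_eligible", "continuously_insured", "not_hospital_outpatient")

_SETTINGS = {"outpatient", "inpatient", "hospital_outpatient"}


class ValidationError(ValueError):
    """Raised when an input table violates its schema."""


def quarter_of(d: date) -> int:
    return (d.month - 1) // 3 + 1


def _parse_dates(series: pd.Series, table: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    if parsed.isna().any():
        bad = series.index[parsed.isna()].tolist()[:5]
        raise ValidationError(f"{table}: unparseable date at row index {bad}")
    return parsed


def confirm_diagnosis(records: pd.DataFrame, year: int) -> bool:
    """Confirmed-diagnosis rule for one patient's diagnosis records.

    True iff, within ``year``, the diagnosis appears in >= 2 distinct
    calendar quarters in the outpatient setting or >= 1 time in the
    inpatient setting.
    """
    if len(records) == 0:
        return False
    dates = _parse_dates(records["date"], "diagnoses")
    in_year = dates.dt.year == year
    if ((records["setting"] == "inpatient") & in_year).any():
        return True
    out = in_year & (records["setting"] == "outpatient")
    quarters = dates[out].dt.quarter
    return quarters.nunique() >= 2


def age_filter(birth_year, window: tuple[int, int] = (2003, 2006)) -> bool:
    """True iff the birth year falls inside the inclusive eligibility window."""
    if birth_year is None or pd.isna(birth_year):
        raise ValidationError("missing birth_year")
    return window[0] <= int(birth_year) <= window[1]


def flag_hospital_outpatient(
    events: pd.DataFrame,
    window: tuple[date, date],
    min_quarters: int = 8,
) -> bool:
    """True iff hospital-outpatient events occur in >= min_quarters distinct quarters."""
    if len(events) == 0:
        return False
    hosp = events[events["setting"] == "hospital_outpatient"]
    if len(hosp) == 0:
        return False
    dates = _parse_dates(hosp["date"], "events")
    inside = (dates >= pd.Timestamp(window[0])) & (dates <= pd.Timestamp(window[1]))
    dates = dates[inside]
    distinct = (dates.dt.year * 4 + dates.dt.quarter).nunique()
    return distinct >= min_quarters


def parse_coverage(spec: str) -> list[tuple[date, date]]:
    """Parse a coverage string ``start/end[;start/end...]`` into date ranges."""
    intervals = []
    for part in str(spec).split(";"):
        try:
            a, b = part.split("/")
            intervals.append((date.fromisoformat(a.strip()), date.fromisoformat(b.strip())))
        except ValueError as exc:
            raise ValidationError(f"invalid coverage interval {part!r}") from exc
    return sorted(intervals)


def continuously_insured(coverage: str, required: tuple[date, date]) -> bool:
    """True iff coverage intervals span ``required`` with no gap of >= 1 day."""
    intervals = parse_coverage(coverage)
    start, end = required
    cursor = start
    for a, b in intervals:
        if a > cursor:
            break
        cursor = max(cursor, b + timedelta(days=1))
    return cursor > end


@dataclass
class CohortFlags:
    """Per-patient audit of every inclusion rule."""

    patient_id: str
    confirmed_dx: bool
    age_eligible: bool
    continuously_insured: bool
    hospital_outpatient: bool

    @property
    def included(self) -> bool:
        return (
            self.confirmed_dx
            and self.age_eligible
            and self.continuously_insured
            and not self.hospital_outpatient
        )


_REQUIRED_COLUMNS = {
    "patients": {"patient_id", "birth_year", "coverage"},
    "diagnoses": {"patient_id", "date", "setting", "code"},
    "events": {"patient_id", "date", "event_code", "setting"},
    "hospitalizations": {"patient_id", "date"},
}


def _validate_schema(tables) -> None:
    for name, required in _REQUIRED_COLUMNS.items():
        if name not in tables:
            raise ValidationError(f"missing input table {name!r}")
        missing = required - set(tables[name].columns)
        if missing:
            raise ValidationError(f"table {name!r} lacks columns {sorted(missing)}")
        if "setting" in tables[name].columns:
            bad = set(tables[name]["setting"].dropna()) - _SETTINGS
            if bad:
                raise ValidationError(f"table {name!r} has unknown settings {sorted(bad)}")


def select_cohort(
    tables: dict[str, pd.DataFrame],
    observation_window: tuple[date, date] = (date(2017, 1, 1), date(2019, 12, 31)),
    insurance_window: tuple[date, date] = (date(2016, 1, 1), date(2019, 12, 31)),
    lookback_year: int = 2016,
    birth_year_window: tuple[int, int] = (2003, 2006),
    hospital_outpatient_min_quarters: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply all inclusion rules and report per-rule attrition.

    Returns ``(cohort, flags, attrition)``: the included patient rows, the
    per-patient rule audit, and an attrition dict counting removals by the
    first failing rule in :data:`RULE_ORDER`.
    """
    _validate_schema(tables)
    patients = tables["patients"]

    # vectorized confirmed-diagnosis rule
    diag = tables["diagnoses"].copy()
    if len(diag):
        ddates = _parse_dates(diag["date"], "diagnoses")
        diag["_year"] = ddates.dt.year
        diag["_q"] = ddates.dt.quarter
        in_year = diag[diag["_year"] == lookback_year]
        inpat = set(in_year.loc[in_year["setting"] == "inpatient", "patient_id"])
        out = in_year[in_year["setting"] == "outpatient"]
        nq = out.groupby("patient_id")["_q"].nunique()
        confirmed = set(nq.index[nq >= 2]) | inpat
    else:
        confirmed = set()

    # vectorized hospital-outpatient rule
    ev = tables["events"]
    hosp_ev = ev[ev["setting"] == "hospital_outpatient"]
    if len(hosp_ev):
        hdates = _parse_dates(hosp_ev["date"], "events")
        inside = (hdates >= pd.Timestamp(observation_window[0])) & (
            hdates <= pd.Timestamp(observation_window[1])
        )
        hosp_ev = hosp_ev[inside]
        hdates = hdates[inside]
        qcount = (
            pd.DataFrame({"patient_id": hosp_ev["patient_id"], "q": hdates.dt.year * 4 + hdates.dt.quarter})
            .groupby("patient_id")["q"]
            .nunique()
        )
        hosp_out = set(qcount.index[qcount >= hospital_outpatient_min_quarters])
    else:
        hosp_out = set()

    rows = []
    for _, p in patients.iterrows():
        rows.append(
            CohortFlags(
                patient_id=p["patient_id"],
                confirmed_dx=p["patient_id"] in confirmed,
                age_eligible=age_filter(p["birth_year"], birth_year_window),
                continuously_insured=continuously_insured(p["coverage"], insurance_window),
                hospital_outpatient=p["patient_id"] in hosp_out,
            )
        )
    flags = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "confirmed_dx": [r.confirmed_dx for r in rows],
            "age_eligible": [r.age_eligible for r in rows],
            "continuously_insured": [r.continuously_insured for r in rows],
            "hospital_outpatient": [r.hospital_outpatient for r in rows],
            "included": [r.included for r in rows],
        }
    )

    # first-failing-rule attribution
    fail = {
        "confirmed_dx": ~flags["confirmed_dx"],
        "age_eligible": ~flags["age_eligible"],
        "continuously_insured": ~flags["continuously_insured"],
        "not_hospital_outpatient": flags["hospital_outpatient"],
    }
    attributed = pd.Series(False, index=flags.index)
    removed = {}
    for rule in RULE_ORDER:
        hit = fail[rule] & ~attributed
        removed[rule] = int(hit.sum())
        attributed |= hit
    attrition = {
        "n_input": int(len(patients)),
        "n_included": int(flags["included"].sum()),
        "removed": removed,
    }

    cohort = patients[patients["patient_id"].isin(flags.loc[flags["included"], "patient_id"])]
    return cohort.reset_index(drop=True), flags, attrition
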