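"""State-sequence encoding of care events across three dimensions.

Six binary care events are grouped into three dimensions:

* ``hcp_contact`` (quarterly): a T1DM-related outpatient contact with a
  GP / pediatrician / internist. States: ``O`` (contact) / ``N`` (none).
* ``diagnostics`` (quarterly): HbA1c measurement (H) and a prescription of
  at least 200 blood-glucose test strips in the quarter (B). States:
  ``N``, ``H``, ``B``, ``HB``.
* ``screening`` (annual): retinopathy (R), cholesterol (C), thyroid (T)
  screening. States: the 8 presence combinations in fixed letter order
  R, C, T — ``N``, ``R``, ``C``, ``T``, ``RC``, ``RT``, ``CT``, ``RCT``.

Each included patient gets one sequence per dimension over the observation
window: 12 quarterly states for the two quarterly dimensions, 3 annual
states for screening. Intervals are half-open ``[start, end)``; an event
dated exactly on a boundary belongs to the later interval. Test-strip
quantities are summed within a quarter before the threshold is applied.
HbA1c and contact events count only in the outpatient setting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_CODES = (
    "OUTPATIENT_CONTACT",
    "HBA1C",
    "STRIPS_RX",
    "RETINOPATHY_SCREEN",
    "CHOLESTEROL_SCREEN",
    "THYROID_SCREEN",
)


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class StateAlphabet:
    """The state set of one dimension: all combinations of its event flags."""

    dimension: str
    granularity: str  # "quarter" | "year"
    flags: tuple[str, ...]  # single-letter flag per event, in label order
    states: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        labels = []
        for mask in range(2 ** len(self.flags)):
            label = "".join(f for i, f in enumerate(self.flags) if mask >> i & 1)
            labels.append(label or "N")
        # special-case the two-state contact alphabet: O present, N absent
        object.__setattr__(self, "states", tuple(labels))

    def label(self, present: Sequence[bool]) -> str:
        lab = "".join(f for f, p in zip(self.flags, present) if p)
        return lab or "N"


HCP_ALPHABET = StateAlphabet("hcp_contact", "quarter", ("O",))
DIAGNOSTICS_ALPHABET = StateAlphabet("diagnostics", "quarter", ("H", "B"))
SCREENING_ALPHABET = StateAlphabet("screening", "year", ("R", "C", "T"))

ALPHABETS = {
    "hcp_contact": HCP_ALPHABET,
    "diagnostics": DIAGNOSTICS_ALPHABET,
    "screening": SCREENING_ALPHABET,
}
DIMENSIONS = tuple(ALPHABETS)


@dataclass(frozen=True)
class StateSequence:
    """One patient's trajectory in one dimension."""

    patient_id: str
    dimension: str
    states: tuple[str, ...]

    def __post_init__(self):
        alphabet = ALPHABETS[self.dimension].states
        bad = set(self.states) - set(alphabet)
        if bad:
            raise SequenceError(f"states {sorted(bad)} not in {self.dimension} alphabet")


def build_timeline(
    window: tuple[date, date], granularity: str
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Half-open interval grid covering the observation window.

    ``window`` is (start, inclusive end); it must cover whole calendar
    quarters (for ``granularity="year"``, whole calendar years).
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1]) + pd.Timedelta(days=1)
    if granularity == "quarter":
        freq = "QS"
    elif granularity == "year":
        freq = "YS"
    else:
        raise SequenceError(f"unknown granularity {granularity!r}")
    edges = pd.date_range(start, end, freq=freq)
    if len(edges) < 2 or edges[0] != start or edges[-1] != end:
        raise SequenceError(
            f"window {window} is not aligned to {granularity} boundaries"
        )
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _interval_index(dates: pd.Series, timeline) -> np.ndarray:
    """Index of the half-open interval containing each date (-1 if outside)."""
    edges = [iv[0] for iv in timeline] + [timeline[-1][1]]
    idx = np.searchsorted(pd.DatetimeIndex(edges).asi8, dates.astype("int64").to_numpy(), side="right") - 1
    idx[(idx < 0) | (idx >= len(timeline))] = -1
    return idx


def _flag_matrices(
    events: pd.DataFrame,
    patient_ids: Sequence[str],
    timeline,
    dimension: str,
    strips_threshold: float,
) -> np.ndarray:
    """Boolean array (n_patients, n_intervals, n_flags) for one dimension."""
    pid_index = pd.Index(patient_ids)
    n, m = len(pid_index), len(timeline)

    ev = events[events["patient_id"].isin(pid_index)].copy()
    dates = pd.to_datetime(ev["date"], format="%Y-%m-%d")
    ev["_iv"] = _interval_index(dates, timeline)
    outside = ev["_iv"] < 0
    if outside.any():
        logger.warning(
            "%d events fall outside the observation window and are ignored",
            int(outside.sum()),
        )
        ev = ev[~outside]
    ev["_p"] = pid_index.get_indexer(ev["patient_id"])

    def presence(mask: pd.Series) -> np.ndarray:
        out = np.zeros((n, m), dtype=bool)
        sub = ev[mask]
        out[sub["_p"].to_numpy(), sub["_iv"].to_numpy()] = True
        return out

    if dimension == "hcp_contact":
        flags = [presence((ev["event_code"] == "OUTPATIENT_CONTACT") & (ev["setting"] == "outpatient"))]
    elif dimension == "diagnostics":
        h = presence((ev["event_code"] == "HBA1C") & (ev["setting"] == "outpatient"))
        strips = ev[ev["event_code"] == "STRIPS_RX"]
        total = np.zeros((n, m))
        if len(strips):
            qty = strips["quantity"].fillna(0.0).to_numpy(dtype=float)
            if (qty < 0).any():
                raise SequenceError("negative STRIPS_RX quantity")
            np.add.at(total, (strips["_p"].to_numpy(), strips["_iv"].to_numpy()), qty)
        flags = [h, total >= strips_threshold]
    elif dimension == "screening":
        flags = [
            presence(ev["event_code"] == code)
            for code in ("RETINOPATHY_SCREEN", "CHOLESTEROL_SCREEN", "THYROID_SCREEN")
        ]
    else:
        raise SequenceError(f"unknown dimension {dimension!r}")
    return np.stack(flags, axis=-1)


def encode_cohort(
    events: pd.DataFrame,
    patient_ids: Sequence[str],
    window: tuple[date, date],
    strips_threshold: float = 200,
) -> dict[str, pd.DataFrame]:
    """Encode every patient's three sequences at once.

    Returns one wide DataFrame per dimension (index = patient_id, one
    column per interval, values = state labels). Row order follows
    ``patient_ids``; the result is independent of event row order.
    """
    out = {}
    for dim, alphabet in ALPHABETS.items():
        timeline = build_timeline(window, alphabet.granularity)
        flags = _flag_matrices(events, patient_ids, timeline, dim, strips_threshold)
        # map each flag combination to its canonical label
        weights = 1 << np.arange(flags.shape[-1])
        codes = (flags * weights).sum(axis=-1)
        labels = np.array(alphabet.states, dtype=object)
        out[dim] = pd.DataFrame(
            labels[codes],
            index=pd.Index(patient_ids, name="patient_id"),
            columns=[f"iv{j}" for j in range(flags.shape[1])],
        )
    return out


def encode_dimension(
    events: pd.DataFrame,
    dimension: str,
    timeline,
    strips_threshold: float = 200,
) -> StateSequence:
    """Encode a single patient's events in one dimension.

    ``events`` must belong to exactly one patient. The state of each
    interval is the combination of event flags observed inside it.
    """
    pids = events["patient_id"].unique()
    if len(pids) > 1:
        raise SequenceError(f"events belong to multiple patients: {pids[:3]}")
    pid = str(pids[0]) if len(pids) else "?"
    alphabet = ALPHABETS[dimension]
    flags = _flag_matrices(events, [pid], timeline, dimension, strips_threshold)[0]
    states = tuple(alphabet.label(iv) for iv in flags)
    return StateSequence(patient_id=pid, dimension=dimension, states=states)


@dataclass(frozen=True)
class AdherenceReference:
    """Ideal guideline care over the 3-year window.

    Quarterly outpatient contact, quarterly HbA1c plus >= 200 test strips,
    and over the three years at least two retinopathy-screen years, two
    thyroid-screen years and one cholesterol-screen year.
    """

    contact_quarters: int = 12
    hba1c_quarters: int = 12
    strips_quarters: int = 12
    retinopathy_years: int = 2
    thyroid_years: int = 2
    cholesterol_years: int = 1


def assess_adherence(
    sequences: Iterable[StateSequence],
    reference: AdherenceReference = AdherenceReference(),
) -> dict:
    """Evaluate one patient's three sequences against the guideline ideal.

    Returns per-requirement booleans, the underlying counts, and
    ``perfect`` = all requirements met.
    """
    by_dim = {s.dimension: s for s in sequences}
    missing = set(DIMENSIONS) - set(by_dim)
    if missing:
        raise SequenceError(f"missing dimensions: {sorted(missing)}")
    hcp, diag, scr = (by_dim[d].states for d in DIMENSIONS)

    counts = {
        "contact_quarters": sum(s == "O" for s in hcp),
        "hba1c_quarters": sum("H" in s for s in diag),
        "strips_quarters": sum("B" in s for s in diag),
        "retinopathy_years": sum("R" in s for s in scr),
        "cholesterol_years": sum("C" in s for s in scr),
        "thyroid_years": sum("T" in s for s in scr),
    }
    met = {
        "contact": counts["contact_quarters"] >= reference.contact_quarters,
        "hba1c": counts["hba1c_quarters"] >= reference.hba1c_quarters,
        "strips": counts["strips_quarters"] >= reference.strips_quarters,
        "retinopathy": counts["retinopathy_years"] >= reference.retinopathy_years,
        "thyroid": counts["thyroid_years"] >= reference.thyroid_years,
        "cholesterol": counts["cholesterol_years"] >= reference.cholesterol_years,
    }
    return {"requirements": met, "counts": counts, "perfect": all(met.values())}


def sequences_from_wide(wide: pd.DataFrame, dimension: str) -> list[StateSequence]:
    """Convert a wide per-dimension table into StateSequence objects."""
    return [
        StateSequence(patient_id=str(pid), dimension=dimension, states=tuple(row))
        for pid, row in zip(wide.index, wide.to_numpy(dtype=object))
    ]
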