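"""Applying a code list to patient event streams to flag cases.

A patient is a case when their clinical/referral events contain at least
``min_codes`` events whose code is on the list; onset is dated to the first
qualifying event. One matching code is ordinarily enough — patients with a
chronic condition accumulate many — but requiring two or more guards
against isolated recording errors. Matching between event codes and list
codes is exact string equality; prefix semantics belong to the search
stage, never to case finding.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .codelist import CodeList
from .errors import EmptyCodeListError, InvalidDateError
from .lookups import resolve_delimiter

EVENT_TABLES = ("clinical", "referral")


@dataclass(frozen=True)
class PatientEvent:
    """One coded event: a diagnosis, symptom or referral entry."""

    patient_id: str
    event_date: dt.date
    code: str
    table: str = "clinical"  # "clinical" or "referral"

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not isinstance(self.event_date, dt.date):
            raise InvalidDateError(f"event_date must be a date, got {self.event_date!r}")


@dataclass(frozen=True)
class CaseRecord:
    """A flagged patient with onset date and the codes that matched."""

    patient_id: str
    first_event_date: dt.date
    n_matching_events: int
    matched_codes: frozenset[str]


def _parse_date(value: str, context: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise InvalidDateError(f"bad {context} date {value!r}: {exc}") from None


def read_events(path, delimiter: str = "comma") -> list[PatientEvent]:
    """Read an event table (patient_id, event_date ISO-8601, code, table).

    Impossible dates are rejected here, not silently dropped downstream.
    Codes absent from any lookup are permitted — real extracts contain
    them — and simply never match a list.
    """
    sep = resolve_delimiter(delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    events = []
    for r in frame.itertuples(index=False):
        table = getattr(r, "table", "clinical") or "clinical"
        events.append(
            PatientEvent(
                patient_id=r.patient_id,
                event_date=_parse_date(r.event_date, "event"),
                code=r.code,
                table=table,
            )
        )
    return events


def find_cases(
    events: Iterable[PatientEvent],
    codelist: CodeList,
    min_codes: int = 1,
    distinct_dates: bool = False,
) -> list[CaseRecord]:
    """Flag patients with at least ``min_codes`` list-code events.

    Events are counted per occurrence: the same code on different dates
    counts separately. With ``distinct_dates`` the threshold instead counts
    distinct event dates, guarding against duplicate same-day entries.
    Clinical and referral events are treated alike; concatenate the two
    tables before calling. Output is sorted by patient_id.
    """
    if min_codes < 1:
        raise ValueError(f"min_codes must be >= 1, got {min_codes}")
    if len(codelist) == 0:
        raise EmptyCodeListError("cannot find cases with an empty code list")
    codes = codelist.codes

    per_patient: dict[str, list[PatientEvent]] = {}
    for ev in events:
        if ev.code in codes:
            per_patient.setdefault(ev.patient_id, []).append(ev)

    cases = []
    for pid in sorted(per_patient):
        evs = per_patient[pid]
        n = len({e.event_date for e in evs}) if distinct_dates else len(evs)
        if n >= min_codes:
            cases.append(
                CaseRecord(
                    patient_id=pid,
                    first_event_date=min(e.event_date for e in evs),
                    n_matching_events=n,
                    matched_codes=frozenset(e.code for e in evs),
                )
            )
    return cases


@dataclass(frozen=True)
class CaseComparison:
    """Overlap between two case sets built on the same event table."""

    a_only: frozenset[str]
    b_only: frozenset[str]
    both: frozenset[str]
    onset_diff_days: dict[str, int]  # A.first − B.first, shared patients only

    @property
    def n_a_only(self) -> int:
        return len(self.a_only)

    @property
    def n_b_only(self) -> int:
        return len(self.b_only)

    @property
    def n_both(self) -> int:
        return len(self.both)


def compare_case_sets(
    cases_a: Sequence[CaseRecord], cases_b: Sequence[CaseRecord]
) -> CaseComparison:
    """Partition the union of patients and difference shared onset dates."""
    a = {c.patient_id: c for c in cases_a}
    b = {c.patient_id: c for c in cases_b}
    shared = a.keys() & b.keys()
    return CaseComparison(
        a_only=frozenset(a.keys() - b.keys()),
        b_only=frozenset(b.keys() - a.keys()),
        both=frozenset(shared),
        onset_diff_days={
            pid: (a[pid].first_event_date - b[pid].first_event_date).days
            for pid in sorted(shared)
        },
    )


def write_cases(cases: Sequence[CaseRecord], path, delimiter: str = "comma") -> None:
    """Write case records as delimited text."""
    sep = resolve_delimiter(delimiter)
    frame = pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in cases],
            "first_event_date": [c.first_event_date.isoformat() for c in cases],
            "n_matching_events": [c.n_matching_events for c in cases],
            "matched_codes": [";".join(sorted(c.matched_codes)) for c in cases],
        }
    )
    frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_cases(path, delimiter: str = "comma") -> list[CaseRecord]:
    sep = resolve_delimiter(delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    return [
        CaseRecord(
            patient_id=r.patient_id,
            first_event_date=_parse_date(r.first_event_date, "case onset"),
            n_matching_events=int(r.n_matching_events),
            matched_codes=frozenset(
                c for c in r.matched_codes.split(";") if c
            ),
        )
        for r in frame.itertuples(index=False)
    ]
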