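"""Annual prevalence and incidence by UK financial year.

Rates are computed over financial years (1 April – 31 March, labelled
"2000/01"), the period over which UK pay-for-performance registers report.

Definitions
-----------
For a financial year Y with span [1 Apr, 31 Mar]:

* **prevalence**: denominator — patients whose registration interval
  overlaps Y at all; numerator — those among them whose first qualifying
  event is on or before the last day of Y. Once a case, always a case.
* **incidence**: numerator — patients whose first event falls inside Y and
  who are registered during Y; denominator — patients registered during Y
  with no first event before Y starts (the population still at risk).

The registration-overlap denominator is the simplest defensible choice; a
mid-year census or person-years denominator would change levels slightly
but not the code-list comparisons this module exists for. Patients whose
first event falls in a year they were never registered in are excluded
from incidence and logged, never silently dropped.

Rates are stored as exact proportions; text output renders them as
percentages to 4 decimal places. A zero denominator yields NaN (flagged),
never a silent 0.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .casefinder import CaseRecord, _parse_date
from .errors import GridMismatchError, MissingRegistrationError
from .lookups import resolve_delimiter

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class Registration:
    """One patient's (single) registration spell; reg_end None = still registered."""

    patient_id: str
    sex: str
    reg_start: dt.date
    reg_end: dt.date | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.reg_end is not None and self.reg_start > self.reg_end:
            raise ValueError(
                f"registration for {self.patient_id} ends before it starts"
            )


def financial_year(d: dt.date) -> str:
    """Label the UK financial year containing a date: 2000-04-01..2001-03-31 → "2000/01"."""
    y = d.year if d.month >= 4 else d.year - 1
    return f"{y}/{(y + 1) % 100:02d}"


def fy_start_year(label: str) -> int:
    return int(label.split("/")[0])


def fy_span(label: str) -> tuple[dt.date, dt.date]:
    """First and last calendar day of a financial year label."""
    y = fy_start_year(label)
    return dt.date(y, 4, 1), dt.date(y + 1, 3, 31)


def year_labels(first_start_year: int, last_start_year: int) -> list[str]:
    """Labels for consecutive financial years, e.g. (1999, 2001) → ['1999/00', '2000/01', '2001/02']."""
    if last_start_year < first_start_year:
        raise ValueError("year range is reversed")
    return [f"{y}/{(y + 1) % 100:02d}" for y in range(first_start_year, last_start_year + 1)]


def read_registrations(path, delimiter: str = "comma") -> list[Registration]:
    """Read a registration table (patient_id, sex, reg_start, reg_end; blank reg_end = open)."""
    sep = resolve_delimiter(delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    regs = []
    for r in frame.itertuples(index=False):
        end = getattr(r, "reg_end", "")
        regs.append(
            Registration(
                patient_id=r.patient_id,
                sex=r.sex,
                reg_start=_parse_date(r.reg_start, "reg_start"),
                reg_end=_parse_date(end, "reg_end") if end else None,
            )
        )
    return regs


def write_registrations(regs: Sequence[Registration], path, delimiter: str = "comma") -> None:
    sep = resolve_delimiter(delimiter)
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in regs],
            "sex": [r.sex for r in regs],
            "reg_start": [r.reg_start.isoformat() for r in regs],
            "reg_end": [r.reg_end.isoformat() if r.reg_end else "" for r in regs],
        }
    )
    frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


_FAR_FUTURE = dt.date(9999, 12, 31)


def _patient_arrays(cases: Sequence[CaseRecord], regs: Sequence[Registration]):
    """Align registrations and case onsets into numpy arrays; validate coverage."""
    reg_ids = {r.patient_id for r in regs}
    missing = {c.patient_id for c in cases} - reg_ids
    if missing:
        raise MissingRegistrationError(missing)
    onset = {c.patient_id: c.first_event_date for c in cases}
    start = np.array([r.reg_start.toordinal() for r in regs])
    end = np.array(
        [(r.reg_end or _FAR_FUTURE).toordinal() for r in regs]
    )
    first = np.array(
        [onset[r.patient_id].toordinal() if r.patient_id in onset else -1 for r in regs]
    )
    sex = np.array([r.sex for r in regs])
    return start, end, first, sex


def _strata(by_sex: bool):
    return ("all",) + (SEXES if by_sex else ())


def _rate_rows(rows: list[dict]) -> pd.DataFrame:
    frame = pd.DataFrame(rows, columns=["year", "stratum", "numerator", "denominator", "rate"])
    return frame


def prevalence(
    cases: Sequence[CaseRecord],
    regs: Sequence[Registration],
    years: Iterable[str],
    by_sex: bool = False,
) -> pd.DataFrame:
    """Per-year prevalence: cases with onset on/before year end over patients registered in it.

    Returns a DataFrame with columns year, stratum, numerator, denominator,
    rate (proportion; NaN where the denominator is 0).
    """
    start, end, first, sex = _patient_arrays(cases, regs)
    rows = []
    for label in years:
        fy0, fy1 = (d.toordinal() for d in fy_span(label))
        registered = (start <= fy1) & (end >= fy0)
        prevalent = registered & (first >= 0) & (first <= fy1)
        for stratum in _strata(by_sex):
            sel = np.ones(len(sex), dtype=bool) if stratum == "all" else sex == stratum
            den = int((registered & sel).sum())
            num = int((prevalent & sel).sum())
            rows.append(
                {
                    "year": label,
                    "stratum": stratum,
                    "numerator": num,
                    "denominator": den,
                    "rate": num / den if den else float("nan"),
                }
            )
    return _rate_rows(rows)


def incidence(
    cases: Sequence[CaseRecord],
    regs: Sequence[Registration],
    years: Iterable[str],
    by_sex: bool = False,
) -> pd.DataFrame:
    """Per-year incidence: first events inside the year over the population at risk.

    A patient incident in a year they were never registered in is excluded
    (and logged); they do not reappear in any other year's numerator — a
    first event happens once.
    """
    start, end, first, sex = _patient_arrays(cases, regs)
    is_case = first >= 0

    # Flag cases whose onset year has no registration overlap at all.
    excluded = np.zeros(len(sex), dtype=bool)
    for i in np.nonzero(is_case)[0]:
        fy0, fy1 = (d.toordinal() for d in fy_span(financial_year(dt.date.fromordinal(int(first[i])))))
        if not (start[i] <= fy1 and end[i] >= fy0):
            excluded[i] = True
    if excluded.any():
        logger.warning(
            "%d case(s) incident outside their registration window; excluded from incidence",
            int(excluded.sum()),
        )

    rows = []
    for label in years:
        fy0, fy1 = (d.toordinal() for d in fy_span(label))
        registered = (start <= fy1) & (end >= fy0)
        # Excluded cases stay at risk while registered pre-onset (censored),
        # but never enter a numerator.
        at_risk = registered & ~(is_case & (first < fy0))
        incident = registered & is_case & (first >= fy0) & (first <= fy1) & ~excluded
        for stratum in _strata(by_sex):
            sel = np.ones(len(sex), dtype=bool) if stratum == "all" else sex == stratum
            den = int((at_risk & sel).sum())
            num = int((incident & sel).sum())
            rows.append(
                {
                    "year": label,
                    "stratum": stratum,
                    "numerator": num,
                    "denominator": den,
                    "rate": num / den if den else float("nan"),
                }
            )
    out = _rate_rows(rows)
    out.attrs["n_excluded_cases"] = int(excluded.sum())
    return out


@dataclass
class RateComparison:
    """Elementwise rate differences between two rate tables on one grid."""

    table: pd.DataFrame  # year, stratum, rate_a, rate_b, rate_diff
    max_diff_rows: pd.DataFrame  # per stratum, the year(s) with the largest difference

    @property
    def max_diff(self) -> float:
        return float(self.table["rate_diff"].max())


def compare_rates(a: pd.DataFrame, b: pd.DataFrame) -> RateComparison:
    """Difference two rate tables (rate_a − rate_b) on an identical grid."""
    key = ["year", "stratum"]
    if not a[key].reset_index(drop=True).equals(b[key].reset_index(drop=True)):
        raise GridMismatchError("rate tables do not share the same (year, stratum) grid")
    merged = a[key].copy()
    merged["rate_a"] = a["rate"].to_numpy()
    merged["rate_b"] = b["rate"].to_numpy()
    merged["rate_diff"] = merged["rate_a"] - merged["rate_b"]
    # Strata with no defined rates (e.g. an empty sex stratum) have no argmax.
    defined = merged.dropna(subset=["rate_diff"])
    if len(defined):
        argmax = (
            defined.loc[defined.groupby("stratum")["rate_diff"].idxmax()]
            .reset_index(drop=True)
        )
    else:
        argmax = merged.iloc[0:0]
    return RateComparison(table=merged, max_diff_rows=argmax)


def write_rates(rates: pd.DataFrame, path, delimiter: str = "comma") -> None:
    """Write a rate table; rates rendered as percentages with 4 decimals."""
    sep = resolve_delimiter(delimiter)
    out = rates[["year", "stratum", "numerator", "denominator"]].copy()
    out["rate_percent"] = [
        "NA" if np.isnan(r) else f"{100 * r:.4f}" for r in rates["rate"]
    ]
    out.to_csv(path, sep=sep, index=False, encoding="utf-8")


def plot_rate_comparison(
    prev_cmp: RateComparison,
    inc_cmp: RateComparison | None = None,
    labels: tuple[str, str] = ("conservative", "qof"),
    path=None,
):
    """Plot paired rate curves (prevalence, optionally incidence below).

    Requires matplotlib (optional dependency); returns the Figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("Prevalence", prev_cmp)] + ([("Incidence", inc_cmp)] if inc_cmp is not None else [])
    fig, axes = plt.subplots(len(panels), 1, figsize=(8, 4 * len(panels)), squeeze=False)
    for ax, (title, cmp_) in zip(axes.ravel(), panels):
        sub = cmp_.table[cmp_.table["stratum"] == "all"]
        ax.plot(sub["year"], 100 * sub["rate_a"], marker="o", label=labels[0])
        ax.plot(sub["year"], 100 * sub["rate_b"], marker="s", label=labels[1])
        ax.set_ylabel(f"{title} (%)")
        ax.tick_params(axis="x", rotation=45)
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
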