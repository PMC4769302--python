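"""Synthetic code dictionaries and patient populations with known ground truth.

Licensed primary-care extracts cannot ship with a toolkit, so every other
module is exercised against generated data whose truth is known by
construction:

* :func:`generate_lookup` builds a code dictionary around a query, planting
  *relevant* rows (true positives: an include stub appears as a standalone
  token), *trap* rows (false positives: a stub appears only buried inside a
  longer word, the "sunstroke" effect when searching for "stroke") and
  inert rows matching nothing.
* :func:`generate_population` builds a registration table and coded event
  stream with planted baseline prevalence and annual incidence, so the
  extract → rates pipeline can be checked against the planted parameters.

Both are deterministic under a fixed seed, which is recorded in the truth
sidecar they emit.
"""

from __future__ import annotations

import datetime as dt
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .casefinder import PatientEvent, write_cases  # noqa: F401  (re-export convenience)
from .codelist import CodeList
from .epirates import Registration, fy_span, write_registrations
from .errors import GenerationError, InfeasibleParametersError
from .lookups import CodeEntry, LookupTable
from .query import KIND_CODE, KIND_WORD, SearchQuery, match_description

# Small packaged corpus for description text; stub-bearing words are filtered
# out per query at generation time so inert rows genuinely match nothing.
_CORPUS = """
acute chronic benign essential familial juvenile senile unspecified bilateral
partial complete recurrent transient severe mild moderate primary secondary
history review screening referral therapy monitoring assessment follow
fracture lesion disorder syndrome disease infection inflammation injury
ulcer cyst polyp nodule tumour swelling rash fever cough pain ache
examination observation consultation immunisation vaccination certificate
knee elbow shoulder ankle wrist spine pelvis femur tibia radius cranium
cardiac renal hepatic gastric dermal ocular aural nasal oral pedal
advice letter report result normal abnormal borderline raised reduced
status onset episode relapse remission recovery discharge admission visit
finding symptom sign test sample culture smear biopsy scan image trace
""".split()

_CONSONANTS = "bcdfgklmnprstvz"
_MAX_DESC_WORDS = 6
_MAX_DESC_LEN = 80

_CODE_ALPHABET = string.ascii_uppercase + string.digits


@dataclass
class LookupTruth:
    """A generated lookup plus the planted labels that make it an oracle."""

    table: LookupTable
    relevant_row_ids: frozenset[int]
    trap_row_ids: frozenset[int]
    seed: int

    def __post_init__(self):
        if self.relevant_row_ids & self.trap_row_ids:
            raise ValueError("relevant and trap row sets must be disjoint")


def _random_code(rng: np.random.Generator) -> str:
    # Read-like 7-character codes: 5 alphanumerics + ".00"-style suffix.
    body = "".join(rng.choice(list(_CODE_ALPHABET), size=5))
    return body[:4] + "." + body[4] + str(rng.integers(0, 10))


def _safe_words(stubs_folded: list[str]) -> list[str]:
    return [w for w in _CORPUS if not any(s in w for s in stubs_folded)]


def _matches_any_exclusion(desc: str, query: SearchQuery) -> bool:
    return any(match_description(t, desc) for t in query.excludes)


def generate_lookup(
    n_rows: int,
    term_set: SearchQuery,
    trap_fraction: float = 0.1,
    seed: int = 0,
    relevant_fraction: float = 0.2,
) -> LookupTruth:
    """Generate a clinical lookup table around a query, with planted labels.

    ``relevant_fraction`` of rows match at least one include term cleanly
    (the stub as its own token, or a code with the requested prefix);
    ``trap_fraction`` match an include stub only as an internal substring of
    a longer word; the remainder match nothing. Relevant and trap rows never
    match an exclusion stub.
    """
    if not 0 <= trap_fraction <= 1:
        raise ValueError("trap_fraction must be in [0, 1]")
    if not 0 <= relevant_fraction <= 1 or trap_fraction + relevant_fraction > 1:
        raise ValueError("relevant_fraction + trap_fraction must be in [0, 1]")
    term_set.validate()
    rng = np.random.default_rng(seed)

    word_terms = [t for t in term_set.includes if t.kind == KIND_WORD]
    code_terms = [t for t in term_set.includes if t.kind == KIND_CODE]
    all_stubs = [s for t in term_set.includes if t.kind == KIND_WORD for s in t.stubs]
    all_stubs += [s for t in term_set.excludes for s in t.stubs]
    folded = [s.casefold() for s in all_stubs]
    for s in all_stubs:
        if len(s) > _MAX_DESC_LEN - 10:
            raise GenerationError(f"stub {s!r} too long to embed in a description")
    safe = _safe_words(folded)
    if len(safe) < _MAX_DESC_WORDS:
        raise GenerationError("term set leaves too few stub-free corpus words")

    n_relevant = round(n_rows * relevant_fraction)
    n_trap = round(n_rows * trap_fraction)
    if n_relevant + n_trap > n_rows:
        raise GenerationError("planted sets exceed n_rows")

    def salad(k: int) -> list[str]:
        return list(rng.choice(safe, size=k))

    def fresh_code() -> str:
        while True:
            code = _random_code(rng)
            if not any(code.startswith(t.stubs[0]) for t in code_terms):
                return code

    def maybe_title(s: str) -> str:
        # Vary capitalisation so case-insensitive matching is actually exercised.
        return s.capitalize() if rng.random() < 0.5 else s

    entries: list[CodeEntry] = []
    relevant_ids, trap_ids = set(), set()
    rid = 0

    for _ in range(n_relevant):
        term = term_set.includes[rng.integers(len(term_set.includes))]
        if term.kind == KIND_CODE:
            code = term.stubs[0] + "".join(rng.choice(list(_CODE_ALPHABET), size=2))
            desc = " ".join(salad(int(rng.integers(2, _MAX_DESC_WORDS))))
        else:
            code = fresh_code()
            words = salad(int(rng.integers(1, _MAX_DESC_WORDS - len(term.stubs) + 1)))
            for stub in term.stubs:
                words.insert(int(rng.integers(len(words) + 1)), maybe_title(stub))
            desc = " ".join(words)
        if _matches_any_exclusion(desc, term_set):  # stubs are pre-filtered; belt and braces
            raise GenerationError(f"planted relevant row matches an exclusion: {desc!r}")
        entries.append(CodeEntry(rid, code, desc, "clinical"))
        relevant_ids.add(rid)
        rid += 1

    if n_trap and not word_terms:
        raise GenerationError("trap rows need at least one word term to embed")
    for _ in range(n_trap):
        term = word_terms[rng.integers(len(word_terms))]
        words = salad(int(rng.integers(1, _MAX_DESC_WORDS - len(term.stubs) + 1)))
        for stub in term.stubs:
            pre = "".join(rng.choice(list(_CONSONANTS), size=int(rng.integers(2, 5))))
            post = "".join(rng.choice(list(_CONSONANTS), size=int(rng.integers(2, 5))))
            words.insert(int(rng.integers(len(words) + 1)), pre + stub + post)
        desc = " ".join(words)
        if _matches_any_exclusion(desc, term_set):
            raise GenerationError(f"planted trap row matches an exclusion: {desc!r}")
        entries.append(CodeEntry(rid, fresh_code(), desc, "clinical"))
        trap_ids.add(rid)
        rid += 1

    while rid < n_rows:
        # Stub-free words can still recreate a phrase stub across a word
        # boundary, so inert rows are rejection-sampled against the query.
        for _ in range(100):
            desc = " ".join(salad(int(rng.integers(2, _MAX_DESC_WORDS + 1))))
            if not any(match_description(t, desc) for t in word_terms):
                break
        else:
            raise GenerationError("could not build an inert description for this term set")
        entries.append(CodeEntry(rid, fresh_code(), desc, "clinical"))
        rid += 1

    table = LookupTable(entries=entries, source="clinical")
    return LookupTruth(
        table=table,
        relevant_row_ids=frozenset(relevant_ids),
        trap_row_ids=frozenset(trap_ids),
        seed=seed,
    )


@dataclass
class PopulationTruth:
    """A generated cohort plus the planted case labels and parameters."""

    registrations: list[Registration]
    events: list[PatientEvent]
    true_cases: dict[str, dt.date]  # patient_id -> onset date
    planted_prevalence: float
    planted_incidence: float
    years: list[int] = field(default_factory=list)  # financial-year start years
    seed: int = 0
    #: patients whose every case event carries a code outside `reference_subset`
    #: (populated when a subset list is supplied; empty otherwise)
    subset_missed_patients: frozenset[str] = frozenset()


def _parse_events_per_case(spec, rng: np.random.Generator):
    """Event-count sampler with a hard minimum of one event per case."""
    if spec is None:
        spec = ("poisson1", 2.0)
    kind, value = spec
    if kind == "constant":
        k = int(value)
        if k < 1:
            raise ValueError("events_per_case constant must be >= 1")
        return lambda: k
    if kind == "poisson1":  # 1 + Poisson(value): truncated at a minimum of 1
        return lambda: 1 + int(rng.poisson(value))
    raise ValueError(f"unknown events_per_case spec {spec!r}")


def generate_population(
    n_patients: int,
    codelist: CodeList,
    prevalence: float,
    annual_incidence: float,
    years: Sequence[int],
    noise_codes: Sequence[str] = ("NOISE.01", "NOISE.02", "NOISE.03"),
    events_per_case=None,
    seed: int = 0,
    reference_subset: CodeList | None = None,
    event_code_style: str = "primary",
) -> PopulationTruth:
    """Generate a closed cohort with planted prevalence and incidence.

    ``years`` are financial-year start years (e.g. ``range(2000, 2012)``).
    Every patient is registered from before the first year through the end
    of the study (open-ended), so the planted parameters identify directly
    with the rate definitions: first-year prevalence ≈ ``prevalence`` and
    per-year incidence ≈ ``annual_incidence``.

    Baseline-prevalent patients get an onset uniformly in the two years
    before the first financial year; incident patients an onset uniform
    within their planted year. Each case's first event is at onset; every
    patient also receives noise-coded events.

    ``event_code_style`` controls how case events are coded. The default,
    "primary", assigns each case one code from ``codelist`` (uniformly) and
    repeats it across their events — mirroring how a chronic diagnosis is
    re-recorded at follow-up, where a handful of codes account for most
    identified cases. "mixed" draws every event's code independently from
    the whole list, which scatters a patient's record across codes and can
    put their first narrow-list event years after true onset.

    When ``reference_subset`` (a sub-list such as a QOF register
    definition) is given, patients none of whose case events carry a subset
    code are recorded in ``subset_missed_patients`` — the planted "missed
    by the narrower definition" truth.
    """
    if event_code_style not in ("primary", "mixed"):
        raise ValueError("event_code_style must be 'primary' or 'mixed'")
    if not 0 <= prevalence <= 1 or not 0 <= annual_incidence <= 1:
        raise ValueError("prevalence and annual_incidence must be proportions")
    if len(codelist) == 0:
        raise ValueError("codelist must be non-empty")
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    total_p = prevalence + len(years) * annual_incidence
    if total_p > 1:
        raise InfeasibleParametersError(
            f"prevalence + cumulative incidence = {total_p:.3f} exceeds 1"
        )
    codes = sorted(codelist.codes)
    overlap = set(noise_codes) & set(codes)
    if overlap:
        raise ValueError(f"noise codes overlap the code list: {sorted(overlap)}")

    rng = np.random.default_rng(seed)
    draw_events = _parse_events_per_case(events_per_case, rng)
    first_fy = fy_span(f"{years[0]}/{(years[0] + 1) % 100:02d}")[0]
    last_fy_end = fy_span(f"{years[-1]}/{(years[-1] + 1) % 100:02d}")[1]
    subset_codes = reference_subset.codes if reference_subset is not None else None

    width = len(str(n_patients))
    registrations, events = [], []
    true_cases: dict[str, dt.date] = {}
    missed: set[str] = set()

    u = rng.random(n_patients)
    sexes = rng.choice(["male", "female"], size=n_patients)
    for i in range(n_patients):
        pid = f"P{i + 1:0{width}d}"
        reg_start = first_fy - dt.timedelta(days=int(rng.integers(365, 5 * 365)))
        registrations.append(
            Registration(patient_id=pid, sex=str(sexes[i]), reg_start=reg_start, reg_end=None)
        )

        onset: dt.date | None = None
        if u[i] < prevalence:
            onset = first_fy - dt.timedelta(days=int(rng.integers(1, 2 * 365)))
        else:
            k = (u[i] - prevalence) / annual_incidence if annual_incidence else np.inf
            if k < len(years):
                fy0, fy1 = fy_span(f"{years[int(k)]}/{(years[int(k)] + 1) % 100:02d}")
                onset = fy0 + dt.timedelta(
                    days=int(rng.integers(0, (fy1 - fy0).days + 1))
                )

        if onset is not None:
            true_cases[pid] = onset
            n_ev = draw_events()
            if event_code_style == "primary":
                ev_codes = [str(rng.choice(codes))] * n_ev
            else:
                ev_codes = [str(c) for c in rng.choice(codes, size=n_ev)]
            span = max((last_fy_end - onset).days, 0)
            dates = [onset] + [
                onset + dt.timedelta(days=int(rng.integers(0, span + 1)))
                for _ in range(n_ev - 1)
            ]
            for d, c in zip(dates, ev_codes):
                table = "referral" if rng.random() < 0.1 else "clinical"
                events.append(PatientEvent(pid, d, c, table))
            if subset_codes is not None and not (set(ev_codes) & subset_codes):
                missed.add(pid)

        n_noise = int(rng.poisson(3))
        for _ in range(n_noise):
            d = reg_start + dt.timedelta(
                days=int(rng.integers(0, (last_fy_end - reg_start).days + 1))
            )
            events.append(PatientEvent(pid, d, str(rng.choice(list(noise_codes))), "clinical"))

    return PopulationTruth(
        registrations=registrations,
        events=events,
        true_cases=true_cases,
        planted_prevalence=prevalence,
        planted_incidence=annual_incidence,
        years=years,
        seed=seed,
        subset_missed_patients=frozenset(missed),
    )


def write_population(pop: PopulationTruth, outdir, delimiter: str = "comma") -> dict[str, Path]:
    """Write registrations.csv, events.csv and truth.json; returns the paths."""
    import pandas as pd

    from .lookups import resolve_delimiter

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sep = resolve_delimiter(delimiter)
    paths = {
        "registrations": outdir / "registrations.csv",
        "events": outdir / "events.csv",
        "truth": outdir / "truth.json",
    }
    write_registrations(pop.registrations, paths["registrations"], delimiter)
    ev = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in pop.events],
            "event_date": [e.event_date.isoformat() for e in pop.events],
            "code": [e.code for e in pop.events],
            "table": [e.table for e in pop.events],
        }
    )
    ev.to_csv(paths["events"], sep=sep, index=False, encoding="utf-8")
    truth = {
        "seed": pop.seed,
        "planted_prevalence": pop.planted_prevalence,
        "planted_incidence": pop.planted_incidence,
        "years": pop.years,
        "true_cases": {pid: d.isoformat() for pid, d in sorted(pop.true_cases.items())},
        "subset_missed_patients": sorted(pop.subset_missed_patients),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8")
    return paths
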