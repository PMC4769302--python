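"""Independent brute-force oracles and random-instance generators.

These deliberately avoid the library's vectorised code paths: matching is
re-derived with plain Python string operations and per-entry loops, so a
bug in the implementation cannot hide in its own oracle.
"""

from __future__ import annotations

import random
import string

from codelistkit.lookups import CodeEntry, LookupTable
from codelistkit.query import (
    KIND_CODE,
    KIND_WORD,
    SearchQuery,
    SearchTerm,
)

LETTERS = string.ascii_lowercase


def oracle_term_matches(term, entry, case_sensitive=False) -> bool:
    """Re-derive one term's match decision with character-level operations."""
    if term.kind == KIND_CODE:
        stub = term.stubs[0]
        # character-by-character prefix comparison, case-sensitive
        if len(entry.code) < len(stub):
            return False
        return all(entry.code[i] == stub[i] for i in range(len(stub)))
    desc = entry.description if case_sensitive else entry.description.casefold()
    for stub in term.stubs:
        s = stub if case_sensitive else stub.casefold()
        if s not in desc:
            return False
    return True


def oracle_search(query: SearchQuery, table: LookupTable, case_sensitive=False):
    """Naive per-entry scan: include-union minus exclusion matches.

    Returns hits sorted by (code, description, row_id), mirroring the
    contract, plus the matched-by mapping.
    """
    hits, matched_by = [], {}
    for entry in table.entries:
        matching = [
            t.raw for t in query.includes if oracle_term_matches(t, entry, case_sensitive)
        ]
        if not matching:
            continue
        desc = entry.description if case_sensitive else entry.description.casefold()
        excluded = any(
            (t.stubs[0] if case_sensitive else t.stubs[0].casefold()) in desc
            for t in query.excludes
        )
        if excluded:
            continue
        hits.append(entry)
        matched_by[entry.row_id] = set(matching)
    hits.sort(key=lambda e: (e.code, e.description, e.row_id))
    return hits, matched_by


def random_word(rng: random.Random, lo=3, hi=8) -> str:
    return "".join(rng.choice(LETTERS) for _ in range(rng.randint(lo, hi)))


def random_lookup(rng: random.Random, n_rows: int) -> LookupTable:
    """Random table; a shared word pool makes term/description collisions likely."""
    pool = [random_word(rng) for _ in range(30)]
    entries = []
    for i in range(n_rows):
        code = "".join(rng.choice(string.ascii_uppercase + string.digits) for _ in range(7))
        words = [rng.choice(pool) for _ in range(rng.randint(1, 6))]
        if rng.random() < 0.3:
            words = [w.capitalize() if rng.random() < 0.5 else w for w in words]
        entries.append(CodeEntry(i, code, " ".join(words), "clinical"))
    return LookupTable(entries=entries, source="clinical")


def random_query(rng: random.Random, table: LookupTable, max_terms=10) -> SearchQuery:
    """Random query biased toward stubs actually present in the table."""
    words = [w for e in table.entries for w in e.description.split()]
    includes, excludes = [], []
    n_terms = rng.randint(1, max_terms)
    for _ in range(n_terms):
        kind = rng.choice(["word", "word", "word", "code", "excl"])
        if kind == "code":
            src = rng.choice(table.entries).code
            stub = src[: rng.randint(1, len(src))]
            includes.append(SearchTerm(kind=KIND_CODE, stubs=(stub,), raw=stub))
        else:
            if words and rng.random() < 0.7:
                w = rng.choice(words)
                stub = w[rng.randint(0, max(0, len(w) - 2)):][: rng.randint(2, 6)]
            else:
                stub = random_word(rng, 2, 5)
            if kind == "excl":
                excludes.append(
                    SearchTerm(kind="exclusion", stubs=(stub,), raw="$" + stub)
                )
            else:
                n_stubs = rng.choice([1, 1, 1, 2])
                stubs = (stub,) + tuple(
                    rng.choice(words)[:4] if words else random_word(rng, 2, 4)
                    for _ in range(n_stubs - 1)
                )
                includes.append(
                    SearchTerm(kind=KIND_WORD, stubs=stubs, raw="+".join(stubs))
                )
    if not includes:
        stub = random_word(rng, 2, 5)
        includes.append(SearchTerm(kind=KIND_WORD, stubs=(stub,), raw=stub))
    return SearchQuery(includes=tuple(includes), excludes=tuple(excludes))


def oracle_find_cases(events, codes: set[str], min_codes=1, distinct_dates=False):
    """Per-patient brute-force case scan returning {pid: (first_date, n, codes)}."""
    out = {}
    patients = sorted({e.patient_id for e in events})
    for pid in patients:
        matching = [e for e in events if e.patient_id == pid and e.code in codes]
        n = len({e.event_date for e in matching}) if distinct_dates else len(matching)
        if matching and n >= min_codes:
            out[pid] = (
                min(e.event_date for e in matching),
                n,
                {e.code for e in matching},
            )
    return out
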