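"""Search-term parsing and lookup-table matching.

This is the computational core of the toolkit: a deliberately
high-sensitivity, low-specificity matcher that turns clinician-supplied
stubs into candidate code lists, accepting false positives (searching for
"stroke" also returns "sunstroke") so that no relevant code is missed.
The candidate list is then narrowed by expert review
(:mod:`codelistkit.codelist`), not by cleverer matching.

Term syntax
-----------
Word terms search the free-text description field:

* a single word-stub matches any description containing it as a substring
  ("angin" matches "Ludwig's angina" and also "Head-banging");
* underscores join word-stubs into an exact phrase
  ("ischemic_cardiomyopathy" searches for "ischemic cardiomyopathy");
* plus signs join word-stubs that must all occur somewhere in one
  description ("alcohol+depend" needs both "alcohol" and "depend");
* a leading dollar sign makes a stub an exclusion: "splen" with
  "$hypersplenism" returns splen-matches except hypersplenism rows.

Code terms are matched exactly as inputted, as a prefix of the code field
("H33" matches H331.11 but not 8H33.00) — in a hierarchical terminology a
prefix search is a subtree search. Codes are case-sensitive; description
matching is case-insensitive by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyQueryError, TermParseError
from .lookups import CodeEntry, LookupTable, resolve_delimiter

KIND_CODE = "code_stub"
KIND_WORD = "word_query"
KIND_EXCL = "exclusion"


@dataclass(frozen=True)
class SearchTerm:
    """A parsed search term.

    ``stubs`` is an ordered tuple of phrase strings: a code_stub or exclusion
    carries exactly one, a word_query carries one per plus-separated part
    (with underscores already replaced by single spaces).
    """

    kind: str
    stubs: tuple[str, ...]
    raw: str

    def __post_init__(self):
        if self.kind in (KIND_CODE, KIND_EXCL) and len(self.stubs) != 1:
            raise ValueError(f"{self.kind} terms carry exactly one stub")
        if self.kind == KIND_WORD and not self.stubs:
            raise ValueError("word_query terms carry at least one stub")


@dataclass(frozen=True)
class SearchQuery:
    """Inclusion terms (code stubs and word queries) plus exclusions."""

    includes: tuple[SearchTerm, ...]
    excludes: tuple[SearchTerm, ...] = ()

    def __post_init__(self):
        for t in self.includes:
            if t.kind not in (KIND_CODE, KIND_WORD):
                raise ValueError(f"include term has kind {t.kind!r}")
        for t in self.excludes:
            if t.kind != KIND_EXCL:
                raise ValueError(f"exclude term has kind {t.kind!r}")

    def validate(self) -> None:
        if not self.includes:
            raise EmptyQueryError("no inclusion terms: a query needs at least one")


def parse_term(raw: str, kind_hint: str = "word") -> SearchTerm:
    """Parse one raw term string.

    ``kind_hint`` is "word" for description terms (full stub syntax) or
    "code" for code stubs, where "$", "+" and "_" are ordinary characters of
    the code itself.
    """
    if kind_hint not in ("word", "code"):
        raise ValueError(f"kind_hint must be 'word' or 'code', got {kind_hint!r}")
    stripped = raw.strip()
    if not stripped:
        raise TermParseError(f"empty term {raw!r}")
    if kind_hint == "code":
        return SearchTerm(kind=KIND_CODE, stubs=(stripped,), raw=stripped)

    if stripped.startswith("$"):
        body = stripped[1:]
        if "$" in body:
            raise TermParseError(f"'$' only allowed at position 0: {raw!r}")
        if "+" in body:
            raise TermParseError(
                f"exclusions are single word-stubs; '+' not allowed: {raw!r}"
            )
        stub = body.replace("_", " ")
        if not stub.strip():
            raise TermParseError(f"exclusion reduces to an empty stub: {raw!r}")
        return SearchTerm(kind=KIND_EXCL, stubs=(stub,), raw=stripped)

    if "$" in stripped:
        raise TermParseError(f"'$' only allowed at position 0: {raw!r}")
    stubs = []
    for part in stripped.split("+"):
        stub = part.replace("_", " ")
        if not stub.strip():
            raise TermParseError(f"term reduces to an empty stub: {raw!r}")
        stubs.append(stub)
    return SearchTerm(kind=KIND_WORD, stubs=tuple(stubs), raw=stripped)


def parse_terms(
    raw_terms: Iterable[str], kind_hint: str = "word"
) -> tuple[list[SearchTerm], list[SearchTerm]]:
    """Parse many terms, splitting includes from exclusions."""
    includes, excludes = [], []
    for raw in raw_terms:
        term = parse_term(raw, kind_hint)
        (excludes if term.kind == KIND_EXCL else includes).append(term)
    return includes, excludes


def read_term_file(path, kind_hint: str = "word") -> tuple[list[SearchTerm], list[SearchTerm]]:
    """Read a plain-text term file: one term per line, '#' lines are comments."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    raws = [ln for ln in (ln.strip() for ln in lines) if ln and not ln.startswith("#")]
    return parse_terms(raws, kind_hint)


def build_query(
    word_terms: Sequence[str] = (), code_terms: Sequence[str] = ()
) -> SearchQuery:
    """Convenience constructor from raw strings."""
    includes, excludes = parse_terms(word_terms, "word")
    code_includes, _ = parse_terms(code_terms, "code")
    return SearchQuery(
        includes=tuple(code_includes) + tuple(includes), excludes=tuple(excludes)
    )


def _fold(text: str, case_sensitive: bool) -> str:
    return text if case_sensitive else text.casefold()


def match_description(
    term: SearchTerm, description: str, case_sensitive: bool = False
) -> bool:
    """Does a word_query or exclusion term match a description?

    A word_query matches iff every stub occurs as a contiguous substring of
    the description (after optional case folding); an exclusion matches iff
    its single stub so occurs. Underscore-derived spaces are matched
    literally — there is no whitespace normalisation and no word-boundary
    logic, which is what makes "angin" match "Head-banging".
    """
    if term.kind == KIND_CODE:
        raise ValueError("match_description does not apply to code stubs")
    desc = _fold(description, case_sensitive)
    return all(_fold(stub, case_sensitive) in desc for stub in term.stubs)


def match_code_prefix(stub: str, code: str) -> bool:
    """Does a code begin with the stub? Case-sensitive, no wildcards."""
    if not stub:
        raise ValueError("code stub must be non-empty")
    return code.startswith(stub)


@dataclass
class SearchResult:
    """Hits of a query against one lookup table.

    ``matched_by`` maps each hit's row_id to the raw strings of the include
    terms that matched it; every hit has at least one.
    """

    hits: list[CodeEntry]
    matched_by: dict[int, set[str]]
    query: SearchQuery
    lookup_source: str
    case_sensitive_descriptions: bool = False

    def __len__(self) -> int:
        return len(self.hits)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: code, description, source, matched_terms."""
        return pd.DataFrame(
            {
                "code": [e.code for e in self.hits],
                "description": [e.description for e in self.hits],
                "source": [e.source for e in self.hits],
                "matched_terms": [
                    ";".join(sorted(self.matched_by[e.row_id])) for e in self.hits
                ],
            }
        )


def run_search(
    query: SearchQuery,
    table: LookupTable,
    case_sensitive_descriptions: bool = False,
) -> SearchResult:
    """Execute a query against a lookup table.

    Hits are the entries matched by at least one include term, minus any
    entry whose description matches an exclusion stub. Exclusions apply to
    the whole hit set, including entries that matched via a code stub: the
    exclusion device exists to thin the review workload, so it must be able
    to veto any hit. Hits are sorted by (code, description, row_id) for
    reproducible diffs between runs.
    """
    query.validate()
    frame = table.to_frame()
    descs = frame["description"]
    codes = frame["code"]
    folded = descs if case_sensitive_descriptions else descs.str.casefold()

    matched_by: dict[int, set[str]] = {}
    include_any = np.zeros(len(frame), dtype=bool)
    for term in query.includes:
        if term.kind == KIND_CODE:
            mask = codes.str.startswith(term.stubs[0]).to_numpy()
        else:
            mask = np.ones(len(frame), dtype=bool)
            for stub in term.stubs:
                needle = stub if case_sensitive_descriptions else stub.casefold()
                mask &= folded.str.contains(needle, regex=False).to_numpy()
        include_any |= mask
        for rid in frame.loc[mask, "row_id"]:
            matched_by.setdefault(int(rid), set()).add(term.raw)

    excluded = np.zeros(len(frame), dtype=bool)
    for term in query.excludes:
        needle = term.stubs[0] if case_sensitive_descriptions else term.stubs[0].casefold()
        excluded |= folded.str.contains(needle, regex=False).to_numpy()

    keep = include_any & ~excluded
    hit_ids = set(int(r) for r in frame.loc[keep, "row_id"])
    hits = sorted(
        (e for e in table.entries if e.row_id in hit_ids),
        key=lambda e: (e.code, e.description, e.row_id),
    )
    matched_by = {rid: terms for rid, terms in matched_by.items() if rid in hit_ids}
    return SearchResult(
        hits=hits,
        matched_by=matched_by,
        query=query,
        lookup_source=table.source,
        case_sensitive_descriptions=case_sensitive_descriptions,
    )


def write_results(result: SearchResult, path, delimiter: str = "comma") -> None:
    """Write search hits as delimited text (code, description, source, matched_terms)."""
    sep = resolve_delimiter(delimiter)
    result.to_frame().to_csv(path, sep=sep, index=False, encoding="utf-8")
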