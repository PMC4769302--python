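"""Review templates and tiered code lists.

The candidate codes returned by a search are exported as a review template,
labelled by an expert panel with one category per row, then assembled into
tiered code lists:

* ``qof`` — the codes a policy framework's business rules already use;
* ``conservative`` — codes each individually sufficient to indicate the
  condition (diagnosis codes by default); must contain the QOF list apart
  from exception-reporting codes;
* ``speculative`` — the conservative list plus ambiguous but strongly
  suggestive codes; a superset of the conservative list.

The superset relations are normative ("should", not mechanical), so
:func:`check_supersets` reports violations rather than raising; a strict
mode is offered for pipelines that want hard failures.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyResultError, UnknownCategoryError, UnreviewedRowsError
from .lookups import resolve_delimiter
from .query import SearchResult

logger = logging.getLogger(__name__)

#: Review categories: seven substantive labels plus an explicit reject label.
CATEGORIES = (
    "diagnosis",
    "management_or_symptom",
    "drug",
    "complication",
    "screening",
    "history_or_resolved",
    "other",
    "not_relevant",
)

TIERS = ("qof", "conservative", "speculative")

#: Default category policy per tier. Conservative admits diagnosis codes only
#: (each must point to the condition and to that alone); this is configuration
#: because for some conditions exclusive drug codes are equally definitive
#: (insulin and diabetes, say). Speculative admits every substantive category.
DEFAULT_TIER_POLICIES: dict[str, frozenset[str]] = {
    "qof": frozenset({"diagnosis"}),
    "conservative": frozenset({"diagnosis"}),
    "speculative": frozenset(c for c in CATEGORIES if c != "not_relevant"),
}

REVIEW_COLUMNS = ("code", "description", "source", "matched_terms", "category", "reviewer_note")


@dataclass(frozen=True)
class ReviewRow:
    """One row of a review template; ``category`` is empty pre-review."""

    code: str
    description: str
    source: str
    matched_terms: str
    category: str = ""
    reviewer_note: str = ""

    def __post_init__(self):
        if self.category and self.category not in CATEGORIES:
            raise UnknownCategoryError(
                f"unknown category {self.category!r} for code {self.code}; "
                f"allowed: {', '.join(CATEGORIES)}"
            )


@dataclass
class CodeList:
    """A reviewed, tiered code list.

    ``entries`` maps code → category (codes unique within a list).
    ``provenance`` carries replicability metadata — a content hash of the
    reviewed rows, the lookup identity, term-file hashes — because a code
    list that cannot be traced to its inputs cannot be audited or reused.
    """

    name: str
    tier: str
    entries: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}, got {self.tier!r}")

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.entries


def make_review_template(result: SearchResult) -> list[ReviewRow]:
    """Turn search hits into unlabelled review rows, one per hit, in result order."""
    if len(result) == 0:
        raise EmptyResultError(
            "search returned no hits; broaden the query before requesting review"
        )
    frame = result.to_frame()
    return [
        ReviewRow(
            code=r.code,
            description=r.description,
            source=r.source,
            matched_terms=r.matched_terms,
        )
        for r in frame.itertuples(index=False)
    ]


def write_review_rows(rows: Sequence[ReviewRow], path, delimiter: str = "comma") -> None:
    sep = resolve_delimiter(delimiter)
    frame = pd.DataFrame([r.__dict__ for r in rows], columns=list(REVIEW_COLUMNS))
    frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_review_rows(path, delimiter: str = "comma") -> list[ReviewRow]:
    """Read a (possibly partially) labelled review file.

    Unknown category labels are rejected immediately — hand-edited files
    invite typos, and a silently dropped label would surface much later as a
    wrong code list. Completeness is only enforced at build time.
    """
    sep = resolve_delimiter(delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in REVIEW_COLUMNS if c not in frame.columns]
    if missing:
        raise UnknownCategoryError(
            f"review file {path} missing columns: {', '.join(missing)}"
        )
    return [
        ReviewRow(**{c: getattr(r, c) for c in REVIEW_COLUMNS})
        for r in frame.itertuples(index=False)
    ]


def _rows_hash(rows: Sequence[ReviewRow]) -> str:
    h = hashlib.sha256()
    for r in rows:
        h.update(repr((r.code, r.description, r.source, r.matched_terms, r.category)).encode())
    return h.hexdigest()[:16]


def build_codelist(
    rows: Sequence[ReviewRow],
    tier: str,
    category_policy: Iterable[str] | None = None,
    name: str = "codelist",
    provenance: Mapping[str, str] | None = None,
) -> CodeList:
    """Assemble a code list from fully reviewed rows.

    Every row must carry a category; rows labelled ``not_relevant`` are never
    admitted regardless of policy. Duplicated codes keep their first-seen
    category and the conflict is logged.
    """
    unreviewed = [r.code for r in rows if not r.category]
    if unreviewed:
        raise UnreviewedRowsError(unreviewed)
    policy = (
        frozenset(category_policy)
        if category_policy is not None
        else DEFAULT_TIER_POLICIES[tier]
    )
    unknown = policy - set(CATEGORIES)
    if unknown:
        raise UnknownCategoryError(f"policy contains unknown categories: {sorted(unknown)}")

    entries: dict[str, str] = {}
    for r in rows:
        if r.category == "not_relevant" or r.category not in policy:
            continue
        if r.code in entries:
            if entries[r.code] != r.category:
                logger.warning(
                    "code %s labelled both %r and %r; keeping first",
                    r.code, entries[r.code], r.category,
                )
            continue
        entries[r.code] = r.category
    if not entries:
        logger.warning("no rows admitted to tier %r under policy %s", tier, sorted(policy))
    prov = dict(provenance or {})
    prov.setdefault("rows_hash", _rows_hash(rows))
    prov.setdefault("n_rows_reviewed", str(len(rows)))
    return CodeList(name=name, tier=tier, entries=entries, provenance=prov)


@dataclass(frozen=True)
class SupersetReport:
    """Result of checking QOF ⊆ conservative ⊆ speculative (non-strict).

    Violations are listed per missing code, sorted, so reports diff cleanly.
    """

    qof_minus_conservative: tuple[str, ...]
    conservative_minus_speculative: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.qof_minus_conservative and not self.conservative_minus_speculative


def check_supersets(
    qof: CodeList,
    conservative: CodeList,
    speculative: CodeList,
    qof_exception_codes: Iterable[str] = (),
) -> SupersetReport:
    """Check the tier containment relations.

    QOF exception-reporting codes (which mark a patient as unsuitable for a
    quality indicator, not as having the condition) are exempt from the
    containment requirement and supplied explicitly.
    """
    exceptions = set(qof_exception_codes)
    missing_cons = sorted((qof.codes - exceptions) - conservative.codes)
    missing_spec = sorted(conservative.codes - speculative.codes)
    return SupersetReport(
        qof_minus_conservative=tuple(missing_cons),
        conservative_minus_speculative=tuple(missing_spec),
    )


def merge_codelists(
    lists: Sequence[CodeList], name: str, tier: str
) -> CodeList:
    """Union of several code lists; first-seen category wins on conflict."""
    if not lists:
        raise ValueError("merge_codelists needs at least one list")
    entries: dict[str, str] = {}
    prov: dict[str, str] = {}
    for i, cl in enumerate(lists):
        for code, cat in cl.entries.items():
            if code in entries:
                if entries[code] != cat:
                    logger.warning(
                        "merge conflict for %s: %r vs %r; keeping first",
                        code, entries[code], cat,
                    )
                continue
            entries[code] = cat
        for k, v in cl.provenance.items():
            prov[f"input{i}.{k}"] = v
        prov[f"input{i}.name"] = cl.name
    return CodeList(name=name, tier=tier, entries=entries, provenance=prov)


def write_codelist(codelist: CodeList, path, delimiter: str = "comma") -> None:
    """Write a code list with provenance as '#' header comments."""
    sep = resolve_delimiter(delimiter)
    path = Path(path)
    lines = [f"# name: {codelist.name}", f"# tier: {codelist.tier}"]
    lines += [f"# {k}: {v}" for k, v in sorted(codelist.provenance.items())]
    frame = pd.DataFrame(
        {"code": list(codelist.entries), "category": list(codelist.entries.values())}
    )
    body = frame.to_csv(sep=sep, index=False)
    path.write_text("\n".join(lines) + "\n" + body, encoding="utf-8")


def read_codelist(path, delimiter: str = "comma") -> CodeList:
    """Read a code list written by :func:`write_codelist`."""
    sep = resolve_delimiter(delimiter)
    path = Path(path)
    name, tier, prov = path.stem, "conservative", {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition(":")
        key, value = key.strip(), value.strip()
        if key == "name":
            name = value
        elif key == "tier":
            tier = value
        else:
            prov[key] = value
    frame = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, comment="#", encoding="utf-8"
    )
    entries = dict(zip(frame["code"], frame["category"]))
    return CodeList(name=name, tier=tier, entries=entries, provenance=prov)
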