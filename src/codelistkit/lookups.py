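"""Reading and validating clinical / product lookup tables.

A lookup table is a delimited-text dictionary mapping codes to free-text
descriptions — for example a primary-care medical dictionary (Read code,
description) or a product dictionary (product code, product name). Codes in
hierarchical clinical terminologies are prefix-significant and
case-significant, so codes are trimmed of surrounding whitespace but never
case-folded or otherwise normalised here. Descriptions are kept verbatim;
all matching semantics live in :mod:`codelistkit.query`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyTableError, MissingColumnError

logger = logging.getLogger(__name__)

SOURCES = ("clinical", "product")

#: Delimiter aliases accepted wherever a dialect is configured.
DELIMITERS = {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}


def resolve_delimiter(delimiter: str) -> str:
    """Map a delimiter name ("comma" / "tab") or literal to the character.

    The delimiter is always explicit configuration, never sniffed from the
    file, so that re-reads are reproducible byte for byte.
    """
    try:
        return DELIMITERS[delimiter]
    except KeyError:
        raise ValueError(
            f"unsupported delimiter {delimiter!r}; use 'comma' or 'tab'"
        ) from None


@dataclass(frozen=True)
class CodeEntry:
    """One row of a lookup table."""

    row_id: int
    code: str
    description: str
    source: str  # "clinical" or "product"


@dataclass
class LookupTable:
    """An ordered collection of :class:`CodeEntry` sharing one source.

    Duplicate (code, description) pairs are permitted — real dictionaries
    carry synonym rows — but ``row_id`` is unique within a table.
    """

    entries: list[CodeEntry]
    source: str
    column_map: Mapping[str, str] = field(default_factory=dict)
    n_trimmed_codes: int = 0  # codes whose surrounding whitespace was removed at read

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        ids = [e.row_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("row_id values must be unique within a LookupTable")
        for e in self.entries:
            if e.source != self.source:
                raise ValueError(
                    f"entry {e.row_id} has source {e.source!r}, table is {self.source!r}"
                )
            if not e.code:
                raise ValueError(f"entry {e.row_id} has an empty code")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_id": [e.row_id for e in self.entries],
                "code": [e.code for e in self.entries],
                "description": [e.description for e in self.entries],
                "source": self.source,
            }
        )


def _read_text_table(path, delimiter: str) -> pd.DataFrame:
    """Read a delimited file as strings, UTF-8 with a logged Latin-1 fallback.

    Legacy dictionary exports are sometimes Latin-1; the fallback keeps them
    readable without silently mangling UTF-8 files.
    """
    sep = resolve_delimiter(delimiter)
    kwargs = dict(sep=sep, dtype=str, keep_default_na=False, skipinitialspace=False)
    try:
        return pd.read_csv(path, encoding="utf-8", **kwargs)
    except UnicodeDecodeError:
        logger.warning("%s is not valid UTF-8; falling back to Latin-1", path)
        return pd.read_csv(path, encoding="latin-1", **kwargs)


def read_lookup(
    path,
    source: str,
    column_map: Mapping[str, str],
    delimiter: str = "comma",
) -> LookupTable:
    """Read a lookup table from delimited text.

    Parameters
    ----------
    path : str or Path
        File with a header row.
    source : {"clinical", "product"}
        Which of the two dictionary files this is.
    column_map : mapping
        Maps the logical fields ``code`` and ``description`` to input column
        names, e.g. ``{"code": "readcode", "description": "desc"}``. A layout
        may have any number of extra columns; they are ignored.
    delimiter : {"comma", "tab"}
        Explicit field delimiter (never sniffed).

    Returns
    -------
    LookupTable
        One entry per data row, in file order; codes trimmed of surrounding
        whitespace, descriptions verbatim. A missing description column value
        becomes the empty string (``keep_default_na=False`` guarantees this).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lookup file not found: {path}")
    if "code" not in column_map:
        raise MissingColumnError("column_map must map the logical field 'code'")
    frame = _read_text_table(path, delimiter)
    code_col = column_map["code"]
    desc_col = column_map.get("description")
    for col in filter(None, (code_col, desc_col)):
        if col not in frame.columns:
            raise MissingColumnError(
                f"column {col!r} not in header {list(frame.columns)} of {path}"
            )
    if len(frame) == 0:
        raise EmptyTableError(f"zero data rows in {path}")

    codes_raw = frame[code_col].astype(str)
    codes = codes_raw.str.strip()
    n_trimmed = int((codes != codes_raw).sum())
    descriptions = (
        frame[desc_col].astype(str) if desc_col else pd.Series([""] * len(frame))
    )
    entries = [
        CodeEntry(row_id=i, code=c, description=d, source=source)
        for i, (c, d) in enumerate(zip(codes, descriptions))
    ]
    return LookupTable(
        entries=entries,
        source=source,
        column_map=dict(column_map),
        n_trimmed_codes=n_trimmed,
    )


def write_lookup(table: LookupTable, path, delimiter: str = "comma") -> None:
    """Write a lookup table back to delimited text (code, description).

    Round-trips exactly with :func:`read_lookup` under the same dialect.
    """
    sep = resolve_delimiter(delimiter)
    frame = table.to_frame()[["code", "description"]]
    frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


@dataclass(frozen=True)
class ValidationReport:
    """Informational quality summary of a lookup table; never mutates it."""

    n_entries: int
    n_empty_descriptions: int
    n_duplicate_pairs: int  # rows beyond the first of each (code, description)
    n_duplicate_codes: int  # codes appearing on more than one row
    n_trimmed_codes: int

    @property
    def n_anomalies(self) -> int:
        return (
            self.n_empty_descriptions
            + self.n_duplicate_pairs
            + self.n_trimmed_codes
        )


def validate_lookup(table: LookupTable) -> ValidationReport:
    """Summarise empty descriptions, duplicate rows/codes and trimmed codes."""
    frame = table.to_frame()
    n_empty = int((frame["description"] == "").sum())
    n_dup_pairs = int(frame.duplicated(subset=["code", "description"]).sum())
    code_counts = frame["code"].value_counts()
    n_dup_codes = int((code_counts > 1).sum())
    return ValidationReport(
        n_entries=len(table),
        n_empty_descriptions=n_empty,
        n_duplicate_pairs=n_dup_pairs,
        n_duplicate_codes=n_dup_codes,
        n_trimmed_codes=table.n_trimmed_codes,
    )


def lookup_from_records(
    records: Iterable[tuple[str, str]], source: str = "clinical"
) -> LookupTable:
    """Build a LookupTable from (code, description) pairs — test/demo helper."""
    entries = [
        CodeEntry(row_id=i, code=code.strip(), description=desc, source=source)
        for i, (code, desc) in enumerate(records)
    ]
    return LookupTable(entries=entries, source=source)
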