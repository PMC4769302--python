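import textwrap

import pytest

from codelistkit import lookup_from_records, read_lookup

#: The canonical worked-example rows: codes whose descriptions exercise every
#: matching rule (prefix vs infix code hits, substring false positives).
PRINTED_ROWS = [
    ("H331.11", "Late onset asthma"),
    ("8H33.00", "Day hospital care"),
    ("J083300", "Ludwig's angina"),
    ("E273100", "Head-banging"),
    ("13HV400", "Seven year itch—marital"),
]

SPLEN_ROWS = [
    ("J690.00", "Splenomegaly"),
    ("J691.00", "Hypersplenism"),
    ("7J36.00", "Splenectomy"),
]


@pytest.fixture
def printed_lookup(tmp_path):
    """The five-row demonstration dictionary, round-tripped through file IO."""
    path = tmp_path / "lookup.csv"
    lines = ["medcode,readcode,desc"]
    lines += [f"{i},{code},\"{desc}\"" for i, (code, desc) in enumerate(PRINTED_ROWS)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return read_lookup(
        path, "clinical", {"code": "readcode", "description": "desc"}, "comma"
    )


@pytest.fixture
def splen_lookup():
    return lookup_from_records(SPLEN_ROWS)


@pytest.fixture
def printed_lookup_path(tmp_path):
    path = tmp_path / "lookup.csv"
    lines = ["code,description"]
    lines += [f"{code},\"{desc}\"" for code, desc in PRINTED_ROWS]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def reviewed_rows():
    """A small fully-reviewed template spanning several categories."""
    from codelistkit import ReviewRow

    return [
        ReviewRow("E100.00", "Schizophrenia", "clinical", "schizo", "diagnosis"),
        ReviewRow("E110.00", "Bipolar disorder", "clinical", "bipolar", "diagnosis"),
        ReviewRow("E120.00", "Psychosis review", "clinical", "psycho", "management_or_symptom"),
        ReviewRow("d1....00", "Antipsychotic drug", "clinical", "psycho", "drug"),
        ReviewRow("E130.00", "Sunstroke", "clinical", "stroke", "not_relevant"),
    ]
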