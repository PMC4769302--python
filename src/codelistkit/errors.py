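"""Exception types raised by codelistkit operations.

Each error corresponds to a declared failure mode of a public operation, so
callers (and the CLI) can distinguish bad inputs from bugs.
"""


class CodelistKitError(Exception):
    """Base class for all codelistkit errors."""


class MissingColumnError(CodelistKitError):
    """A configured logical column is absent from the input file header."""


class EmptyTableError(CodelistKitError):
    """A lookup or event file contained a header but no data rows."""


class TermParseError(CodelistKitError):
    """A search term could not be parsed (empty, or malformed stub syntax)."""


class EmptyQueryError(CodelistKitError):
    """A search query has no inclusion terms (exclusion-only queries are invalid)."""


class EmptyResultError(CodelistKitError):
    """A search result with zero hits where at least one is required."""


class UnreviewedRowsError(CodelistKitError):
    """Review rows still lacking a category label at code-list build time."""

    def __init__(self, codes):
        self.codes = sorted(codes)
        super().__init__(
            "unreviewed rows (empty category) for codes: " + ", ".join(self.codes)
        )


class UnknownCategoryError(CodelistKitError):
    """A review file carries a category label outside the fixed vocabulary."""


class EmptyCodeListError(CodelistKitError):
    """A case-finding run was given a code list with no codes."""


class InvalidDateError(CodelistKitError):
    """An event or registration date could not be parsed as a calendar date."""


class MissingRegistrationError(CodelistKitError):
    """A case patient has no registration row."""

    def __init__(self, patient_ids):
        self.patient_ids = sorted(patient_ids)
        super().__init__(
            "case patients missing from registrations: " + ", ".join(self.patient_ids)
        )


class GridMismatchError(CodelistKitError):
    """Two rate tables do not share the same (year, stratum) grid."""


class InfeasibleParametersError(CodelistKitError):
    """Synthetic-population parameters are jointly impossible (e.g. total case
    probability above 1)."""


class GenerationError(CodelistKitError):
    """Synthetic-lookup construction cannot satisfy the requested term set."""
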