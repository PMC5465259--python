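"""Exception hierarchy for table validation and computation failures.

Validation errors carry *all* offending rows/groups, not just the first,
so a user can fix a hand-curated table in one pass.
"""
from __future__ import annotations


class TrioQpcrError(Exception):
    """Base class for all package errors."""


class SchemaError(TrioQpcrError):
    """A required column is missing or the file cannot be interpreted."""


class ParseError(TrioQpcrError):
    """A cell could not be parsed (e.g. non-numeric CT); names the rows."""


class ValidationError(TrioQpcrError):
    """Typed invariants violated; message lists every offending row/group."""

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = list(problems or [])
        if self.problems:
            message = message + "\n  - " + "\n  - ".join(self.problems)
        super().__init__(message)


class ComputationError(TrioQpcrError):
    """Numeric precondition violated (non-finite input, degenerate denominator)."""
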