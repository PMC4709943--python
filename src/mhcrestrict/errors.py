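"""Exception hierarchy for the toolkit.

All domain errors derive from :class:`MhcRestrictError` so callers (and the
CLI) can catch one base type and map it to a non-zero exit status.
"""

from __future__ import annotations


class MhcRestrictError(Exception):
    """Base class for all toolkit errors."""


# --- nomenclature ---------------------------------------------------------


class InvalidNameError(MhcRestrictError, ValueError):
    """The string cannot be an MHC designation (e.g. empty input)."""


class UnknownDialectError(MhcRestrictError, ValueError):
    """No registered species prefix matches and no dialect hint was given."""


# --- ontology model -------------------------------------------------------


class DuplicateTermError(MhcRestrictError):
    """A term id was registered twice in one ontology."""


class DuplicateLabelError(MhcRestrictError):
    """Two classes in the same branch carry the same label."""


class UnknownTermError(MhcRestrictError, KeyError):
    """A term id or label does not resolve in the ontology."""


class WrongBranchError(MhcRestrictError):
    """A query received a term from the wrong ontology branch."""


class ValidationError(MhcRestrictError):
    """An operation requiring a valid ontology received diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(str(d) for d in self.diagnostics)
        super().__init__(f"ontology failed validation: {lines}")


# --- templates ------------------------------------------------------------


class TemplateFormatError(MhcRestrictError):
    """Malformed template table (ragged row, bad cell), with row context."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class TemplateSchemaError(MhcRestrictError):
    """Template header/pattern rows violate the template schema."""


# --- reasoner -------------------------------------------------------------


class UnsupportedConstructError(MhcRestrictError):
    """A class expression falls outside the implemented logical fragment."""


# --- io -------------------------------------------------------------------


class ExportError(MhcRestrictError):
    """An axiom is not expressible in the requested serialization subset."""


class OboParseError(MhcRestrictError):
    """Malformed OBO input, with a 1-based line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


# --- fixtures -------------------------------------------------------------


class GenerationError(MhcRestrictError):
    """Random-ontology generation received infeasible parameters."""
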