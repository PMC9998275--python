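"""Exception hierarchy shared across the package."""


class AxialTrendsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AxialTrendsError):
    """A required column or field is missing from an input file."""


class ValidationError(AxialTrendsError):
    """An input value violates a table- or record-level constraint."""


class MatchingError(AxialTrendsError):
    """Trait table and phylogeny cannot be reconciled."""


class FormatError(AxialTrendsError):
    """A tree or table file is syntactically or structurally unusable."""


class DomainError(AxialTrendsError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateInputError(DomainError):
    """Input is technically valid but carries no usable signal
    (e.g. zero variance everywhere, all differences zero)."""
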