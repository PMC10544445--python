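"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: SchemaError -> 3, any other
DiabmodError -> 4, usage errors are handled by click (2).
"""


class DiabmodError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DiabmodError):
    """The input table violates the expected layout (missing outcome,
    empty file, wrong column set)."""


class ParseError(DiabmodError):
    """A cell could not be interpreted as a number; names row/column."""


class NoDonorError(DiabmodError):
    """Imputation has no observed values to average for a column/class."""
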