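"""Exception types shared across the package."""


class KanosightError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KanosightError):
    """A required column is missing or a schema mapping is inconsistent."""


class ParseError(KanosightError):
    """An answer value could not be mapped to a canonical level.

    Carries the 1-based data row number when raised while reading a file.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class UndefinedIndexError(KanosightError):
    """Better/Worse are undefined because A+P+M+I = 0 for an attribute."""


class DegenerateTableError(KanosightError):
    """A contingency table has an all-zero row or column (or is too small)."""
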