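"""Exception hierarchy.

``ValidationError`` covers bad inputs and contract violations (CLI exit
code 2); ``FileFormatError`` covers unparsable files (CLI exit code 3).
"""


class ChromDoeError(Exception):
    """Base class for all package errors."""


class ValidationError(ChromDoeError):
    """Invalid argument values or violated preconditions."""


class UnsupportedDesignError(ValidationError):
    """Requested a design geometry the package does not build."""


class DegenerateFactorError(ValidationError):
    """Factor with zero range (high == low)."""


class SingularDesignError(ValidationError):
    """Model matrix is rank deficient; coefficients are not identifiable."""


class FileFormatError(ChromDoeError):
    """A file could not be parsed in the expected layout."""
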