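"""Exception hierarchy used across the package."""


class CmbScreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CmbScreenError):
    """An input violates a documented precondition or invariant."""


class GridMismatchError(ValidationError):
    """Two volumes that must share a voxel grid do not."""


class DimensionalityError(ValidationError):
    """A volume does not have exactly three spatial dimensions."""


class ParseError(ValidationError):
    """A text annotation record could not be parsed.

    Carries the 1-based line number when available.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigurationError(CmbScreenError):
    """A configuration value or registry name is invalid."""


class DegenerateSliceError(CmbScreenError):
    """A slice has too little in-mask signal to be standardized."""


class CapacityError(CmbScreenError):
    """A placement request could not be satisfied; reports what was achieved."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved
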