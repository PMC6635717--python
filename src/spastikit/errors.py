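"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class SpastikitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpastikitError):
    """Invalid or contradictory run configuration."""


class DataError(SpastikitError, ValueError):
    """Input data cannot support the requested computation."""


class NoMovementError(DataError):
    """No movement detected in an angle trace."""


class MovementIncompleteError(DataError):
    """The angle trace never reaches the target extension angle."""
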