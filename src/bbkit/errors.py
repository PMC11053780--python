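"""Exception hierarchy shared across the toolkit.

CLI exit-code mapping: ``SchemaError`` → 2, ``ConfigError`` → 3, everything
else non-zero via typer's default handling.
"""


class BBKitError(Exception):
    """Base class for all toolkit errors."""


class DomainError(BBKitError, ValueError):
    """Input outside the mathematical domain of an operation."""


class InvalidTripletError(DomainError):
    """An NQR frequency pair that would imply an asymmetry parameter > 1."""


class SchemaError(BBKitError):
    """Structural mismatch: wrong keys, misaligned labels, bad headers."""


class ConfigError(BBKitError):
    """Invalid generator or threshold configuration."""


class GeometryError(DomainError):
    """Degenerate coordinates (coincident or collinear atoms)."""


class CatalogError(BBKitError, KeyError):
    """Unknown fixture name."""
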