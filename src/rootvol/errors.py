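"""Exception hierarchy.

All package-specific failures derive from :class:`RootvolError` so callers
(and the CLI) can distinguish bad inputs (exit code 2) from computation
failures (exit code 3).
"""


class RootvolError(Exception):
    """Base class for all rootvol errors."""


class DomainError(RootvolError, ValueError):
    """A geometric argument violates its domain (non-positive or non-finite)."""


class SchemaError(RootvolError, ValueError):
    """A cohort table violates the CSV schema; message carries row/column."""


class InputError(RootvolError, ValueError):
    """A statistical routine received unusable input (length mismatch, n too small)."""


class CalibrationError(RootvolError, ValueError):
    """Projection-factor calibration is impossible (missing volumes, n < 2)."""


class ConfigError(RootvolError, ValueError):
    """A synthetic-cohort configuration field is invalid."""


class EstimationError(RootvolError, RuntimeError):
    """A model fit diverged or the input is degenerate."""


class TransposedAxesWarning(UserWarning):
    """Root width exceeds root length — columns are possibly transposed."""
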