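"""Exception hierarchy for the pipeline.

Errors are split by whether they indicate a bad configuration (exit code 1
from the CLI) or bad/inconsistent data (exit code 2).
"""


class AlphaP1Error(Exception):
    """Base class for all package errors."""


class ConfigError(AlphaP1Error, ValueError):
    """Invalid parameter or configuration value."""


class DataError(AlphaP1Error, ValueError):
    """Invalid or inconsistent data content."""


class SchemaError(DataError):
    """A container or table is missing required structure."""


class PipelineOrderError(DataError):
    """An operation was applied in an invalid pipeline order (unit-tag guard)."""


class NoUsableTrialsError(DataError):
    """Every epoch of a subject was rejected."""


class SingularGeometryError(DataError):
    """Electrode geometry is degenerate (coincident positions)."""


class DegenerateDataError(DataError):
    """A statistic is undefined for the given data (zero variance, constants)."""
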