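"""Exception hierarchy shared across the package."""


class CtDoseAuditError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CtDoseAuditError):
    """A required column or field is missing from an input table."""


class RowValidationError(CtDoseAuditError):
    """A row holds a value that cannot be parsed or violates an invariant."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class DuplicateUidError(CtDoseAuditError):
    """A series UID occurs more than once within one input list."""

    def __init__(self, series_uid: str):
        self.series_uid = series_uid
        super().__init__(f"duplicate series_uid {series_uid!r}")


class RegionLookupError(CtDoseAuditError):
    """No conversion factor is configured for the requested region."""


class WeightMissingError(CtDoseAuditError):
    """A weight-corrected dose was requested for a record without weight."""


class WeightRangeError(CtDoseAuditError):
    """Patient weight lies outside the validity range of the weight model."""


class DiameterRangeError(CtDoseAuditError):
    """Effective diameter lies outside the plausible (cm-scale) range."""


class CalibrationRangeError(CtDoseAuditError):
    """No calibrated regression segment covers (region, scan length)."""


class MapNotConfiguredError(CtDoseAuditError):
    """The diameter-basis linear map requires explicit coefficients."""


class DegenerateDesignError(CtDoseAuditError):
    """The regression design is singular (e.g. constant x)."""


class NoDiagnosticSeriesError(CtDoseAuditError):
    """A study contains no non-scout series."""


class ConfigError(CtDoseAuditError):
    """Invalid configuration (bad proportions, conflicting inputs, ...)."""


class NegativeDoseWarning(UserWarning):
    """A calibrated linear map produced a negative dose; value not clamped."""
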