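"""Exception hierarchy.

Validation/schema/configuration problems (bad inputs) are distinguished from
numerical failures (calibration or fitting did not converge) so the CLI can
map them to distinct exit codes.
"""


class PheretimaRiskError(Exception):
    """Base class for all package errors."""


class ValidationError(PheretimaRiskError):
    """Input data violates a documented invariant (negative value, duplicate id, ...)."""


class SchemaError(ValidationError):
    """A tabular file does not match the expected column schema."""


class ConfigurationError(PheretimaRiskError):
    """A required parameter (detection limit, metal model, ...) is missing or inconsistent."""


class CalibrationError(PheretimaRiskError):
    """No parameter set satisfies the requested calibration constraints."""


class FitError(PheretimaRiskError):
    """Maximum-likelihood fitting failed to converge."""


class DegenerateDataError(FitError):
    """The data carry no information for the requested fit (e.g. zero variance)."""


class SelectionError(PheretimaRiskError):
    """Every candidate family failed to fit; no model can be selected."""
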