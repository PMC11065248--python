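"""Exception types shared across the package."""


class NcdsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NcdsimError):
    """Invalid configuration or fixture content.

    ``fields`` lists every offending field so a bad configuration is reported
    in one pass rather than one field at a time.
    """

    def __init__(self, message, fields=None):
        super().__init__(message)
        self.fields = list(fields) if fields else []


class ModelInputError(NcdsimError):
    """A risk model was handed a profile missing a required field."""


class ImputationError(NcdsimError):
    """Imputation cannot proceed (e.g. a variable with no observed values)."""


class CalibrationError(NcdsimError):
    """Calibration target unreachable or bisection failed to converge."""


class SimulationError(NcdsimError):
    """Invalid simulation state or parameters (e.g. probability out of [0,1])."""
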