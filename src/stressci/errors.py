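"""Exception hierarchy shared across the pipeline stages."""


class StressCIError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StressCIError, ValueError):
    """A caller-supplied parameter is outside its admissible domain."""


class InsufficientDataError(StressCIError, ValueError):
    """Too few observations for the requested fit or decomposition."""


class ConvergenceError(StressCIError, RuntimeError):
    """Nonlinear fit failed to converge; carries best-so-far parameters."""

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class ModelSelectionError(StressCIError, RuntimeError):
    """No candidate baseline family could be fitted."""


class OutOfWindowError(StressCIError, ValueError):
    """Clock time outside the fitted baseline window."""


class DegenerateBaselineError(StressCIError, ValueError):
    """Baseline value below the positivity floor; ratios undefined."""


class DegenerateControlError(StressCIError, ValueError):
    """Control value non-positive; relative change undefined."""


class CollinearityError(StressCIError, ValueError):
    """Design matrix rank-deficient; regression weights unidentifiable."""


class SchemaError(StressCIError, ValueError):
    """Input table does not match the expected column schema."""


class ConfigError(StressCIError, ValueError):
    """Pipeline or design configuration is inconsistent."""


class MissingDataError(StressCIError, ValueError):
    """A required field is absent from a record."""
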