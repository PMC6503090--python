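"""Exception types shared across the pipeline stages."""


class BarotrendError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BarotrendError, ValueError):
    """An input design/calibration/config object is inconsistent or incomplete."""


class CalibrationError(ConfigurationError):
    """A correlation loading is outside [-1, 1] or a target is unattainable."""


class ParameterError(BarotrendError, ValueError):
    """A tuning parameter (gamma, level, fractions ...) is out of range."""


class DegenerateInputError(BarotrendError, ValueError):
    """A statistic is undefined on the given data (zero variance, all ties ...)."""


class MissingCellError(BarotrendError, KeyError):
    """Prediction requested for a (gender, age-class) cell absent from the fit."""
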