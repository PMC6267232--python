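"""Exception hierarchy shared across the package."""


class MncError(Exception):
    """Base class for all package errors."""


class ValidationError(MncError):
    """Input violates a documented invariant (labels, shapes, ranges)."""


class FormatError(MncError):
    """An external artifact could not be parsed into its domain type."""


class ConfigurationError(MncError):
    """A configuration value is outside its admissible range."""


class InputTooShortError(ValidationError):
    """Time series shorter than one epoch."""


class UndefinedPhaseError(ValidationError):
    """Instantaneous phase requested for an identically-zero signal."""


class DegenerateInputError(ValidationError):
    """A statistic is undefined for this input (e.g. all-tied ranks)."""
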