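"""Exception hierarchy shared across the pipeline."""


class MSIError(Exception):
    """Base class for all msi3d errors."""


class ConfigError(MSIError):
    """Invalid configuration or parameter value."""


class InputError(MSIError):
    """Invalid input data (precondition violation)."""


class FormatError(MSIError):
    """Malformed file or unsupported on-disk layout."""


class NormalizationError(MSIError):
    """Spectrum cannot be normalized (e.g. zero total ion count)."""


class RegistrationError(MSIError):
    """Image registration cannot proceed (e.g. blank image)."""


class DependencyError(MSIError):
    """A pipeline stage is missing an upstream artifact."""
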