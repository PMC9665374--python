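"""Exception hierarchy shared across the pipeline stages."""


class PulsewaveError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PulsewaveError, ValueError):
    """Invalid configuration value (bad proportions, non-positive rates...)."""


class UndefinedSnrError(PulsewaveError, ValueError):
    """SNR requested on a signal with no measurable band power."""


class NoCyclesDetected(PulsewaveError, RuntimeError):
    """Beat segmentation found too few cardiac cycles to proceed."""


class InsufficientDataError(PulsewaveError, ValueError):
    """An estimator was given fewer observations than it requires."""


class SchemaError(PulsewaveError, ValueError):
    """An on-disk artifact or feature table does not match the expected schema."""


class EmptyStratumError(PulsewaveError, ValueError):
    """A label definition left one of the two classes empty."""


class FrozenModelError(PulsewaveError, RuntimeError):
    """Attempt to modify or retrain a model after it was frozen."""
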