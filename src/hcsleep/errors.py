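"""Exception hierarchy shared across the package."""


class HcsleepError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HcsleepError, ValueError):
    """Invalid in-memory data or parameters."""


class FormatError(HcsleepError, ValueError):
    """A file on disk does not conform to its expected format."""


class DegenerateInputError(HcsleepError, ValueError):
    """Input is formally valid but has no usable signal (e.g. constant trace)."""


class EmptyStageError(HcsleepError, ValueError):
    """A requested sleep stage is absent from the hypnogram."""


class PlacementError(HcsleepError, RuntimeError):
    """Requested synthetic event density cannot be placed without overlap."""


class ConfigError(HcsleepError, ValueError):
    """Pipeline configuration fails schema validation."""


class DependencyError(HcsleepError, RuntimeError):
    """A pipeline stage's prerequisite output is missing."""
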