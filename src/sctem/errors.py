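"""Exception types shared across the package."""


class SctemError(Exception):
    """Base class for package errors."""


class InvalidParameterError(SctemError, ValueError):
    """A function argument violates its documented precondition."""


class GenerationError(SctemError, RuntimeError):
    """Synthetic-data generation failed after bounded retries."""


class ConfigurationError(SctemError, ValueError):
    """A configuration object or plate/well reference is invalid."""


class FormatError(SctemError, ValueError):
    """A file is malformed; message names the file and line."""


class InsufficientDataError(SctemError, ValueError):
    """Too few observations for the requested statistic."""
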