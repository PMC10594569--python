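"""Exception hierarchy used across the package."""


class QminetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(QminetError, ValueError):
    """An input file or table does not have the expected layout."""


class ValidationError(QminetError, ValueError):
    """A table violates a data-model invariant (e.g. non-positive fluorescence)."""


class ParameterError(QminetError, ValueError):
    """An operation received an out-of-range parameter."""


class PipelineError(QminetError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
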