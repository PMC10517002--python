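"""Exception hierarchy shared across the pipeline."""


class RatseizError(Exception):
    """Base class for all package errors."""


class ValidationError(RatseizError, ValueError):
    """Input violates a documented precondition or invariant."""


class DegenerateSignalError(ValidationError):
    """Signal has no usable structure (constant, zero power, too short)."""


class UnsupportedFormatError(ValidationError):
    """File format not handled by the reader/writer."""


class SelectionError(RatseizError):
    """No training window satisfies the ictal-fraction criterion."""


class PlacementError(ValidationError):
    """Requested event load cannot be placed within the recording."""


class BackboneUnavailableError(RatseizError):
    """Requested classifier backbone has no registered implementation."""
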