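"""Package-specific exception types."""


class ThetanavError(Exception):
    """Base class for errors raised by this package."""


class DegenerateInputError(ThetanavError):
    """Input is structurally valid but statistically degenerate (e.g. zero variance)."""


class InsufficientDataError(ThetanavError):
    """Too little data to compute the requested quantity."""


class BandNotFoundError(ThetanavError):
    """No spectral peak found in the requested search range."""


class ValidationError(ThetanavError):
    """A session file or table failed schema validation."""
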