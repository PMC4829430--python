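"""Exception hierarchy for trace analysis and model fitting."""


class EbcapError(Exception):
    """Base class for package-specific errors."""


class NoWashoutError(EbcapError):
    """No background transition detected in the soluble-tubulin channel."""


class NoCatastropheError(EbcapError):
    """Post-washout trace shows no fast-depolymerisation phase."""


class FitFailureError(EbcapError):
    """A nonlinear fit failed to converge or hit its parameter bounds."""


class InsufficientDataError(EbcapError):
    """Too few samples or tracks to perform the requested operation."""


class UndefinedFractionError(EbcapError):
    """Cap fraction undefined because the end intensity does not exceed lattice."""


class UndefinedCorrelationError(EbcapError):
    """Correlation undefined (constant input)."""


class SchemaError(EbcapError):
    """A track table does not conform to the expected column schema."""
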