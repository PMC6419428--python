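"""Exception hierarchy shared across the package."""


class MIFHHError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MIFHHError):
    """An input file does not conform to the expected tabular format."""


class ValidationError(MIFHHError):
    """Records violate a data-model invariant (duplicates, family mismatch, bad codes)."""


class ConfigurationError(MIFHHError):
    """Inconsistent or invalid model / sampler / simulation configuration."""


class DegenerateInputError(MIFHHError):
    """Input is empty or otherwise too small for the requested computation."""


class UndefinedStatisticError(MIFHHError):
    """The requested statistic is undefined for this input (e.g. single-class AUC)."""
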