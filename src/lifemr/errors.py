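"""Exception hierarchy shared across the pipeline stages."""


class LifemrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LifemrError, ValueError):
    """Invalid or inconsistent simulation / pipeline configuration."""


class HarmonisationError(LifemrError, ValueError):
    """Variant alleles could not be reconciled between summary tables."""


class ProxyLookupError(LifemrError, LookupError):
    """Index variant unavailable in the reference panel for proxy search."""


class UndefinedLDError(LifemrError, ValueError):
    """LD requested for a monomorphic variant."""


class NonIdentifiedError(LifemrError, ValueError):
    """An MR estimate is not identified (e.g. all exposure betas zero)."""


class InsufficientInstrumentsError(LifemrError, ValueError):
    """Too few instruments for the requested estimator."""


class WeakConditionalInstrumentError(LifemrError, ValueError):
    """Exposure beta columns are (near-)collinear in multivariable MR."""


class ScaleMismatchError(LifemrError, ValueError):
    """Results on incompatible scales combined or transformed."""
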