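"""Exception hierarchy shared across the package."""


class FitcloudError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FitcloudError, ValueError):
    """An invalid parameter combination in a spec or config object."""


class DomainError(FitcloudError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class FormatError(FitcloudError, ValueError):
    """A malformed on-disk artifact (CSV/JSON schema violation)."""


class ValidationError(FitcloudError, ValueError):
    """An invalid record, instance or label."""


class DegenerateModelError(FitcloudError, ValueError):
    """Training data that cannot support the requested model."""


class StratificationError(FitcloudError, ValueError):
    """A class too small to be represented in every cross-validation fold."""
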