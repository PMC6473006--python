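"""Shared exception types."""


class FrontoboostError(Exception):
    """Base class for package errors."""


class SpecError(FrontoboostError, ValueError):
    """A cohort / generator specification is invalid."""


class ConfigurationError(FrontoboostError, ValueError):
    """An analysis parameter is outside its valid range."""


class InsufficientDataError(FrontoboostError, ValueError):
    """Too little (unmasked) data for the requested computation."""


class ValidationError(FrontoboostError, ValueError):
    """An input record violates its declared invariants."""


class SingleClassError(FrontoboostError, ValueError):
    """An operation requiring both classes received only one."""


class FormatError(FrontoboostError, ValueError):
    """A file does not follow the expected on-disk layout."""


class MarkerError(FrontoboostError, ValueError):
    """Event markers are missing, unmatched, or crossed."""
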