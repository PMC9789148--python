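"""Exception types shared across the package."""


class GaitPainError(Exception):
    """Base class for package errors."""


class SpecValidationError(GaitPainError, ValueError):
    """A generator or pipeline spec violates one of its invariants.

    The message always names the offending field.
    """


class NoGaitError(GaitPainError, ValueError):
    """No walking content could be located in an acceleration signal."""


class InsufficientDataError(GaitPainError, ValueError):
    """A computation requires more samples, strides or events than supplied."""


class ConfigError(GaitPainError, ValueError):
    """Inconsistent pipeline or filter configuration."""
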