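"""Exception types shared across the package."""


class SmallFieldError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(SmallFieldError, ValueError):
    """A synthetic field / session specification violates its invariants."""


class InvalidInputError(SmallFieldError, ValueError):
    """Numerically invalid input (non-positive size, zero denominator, ...)."""


class InvalidCorrectionError(SmallFieldError, ValueError):
    """A reading-correction factor is zero, negative, or not applicable."""


class BracketingError(SmallFieldError, RuntimeError):
    """Penumbra samples do not bracket the requested dose level."""


class UnsupportedGeometryError(SmallFieldError, ValueError):
    """Unknown sensitive-volume shape or orientation."""


class FixtureSchemaError(SmallFieldError, ValueError):
    """A perturbation-factor fixture is missing required columns."""
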