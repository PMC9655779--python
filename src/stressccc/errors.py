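"""Exception hierarchy shared across the package."""


class StressCCCError(Exception):
    """Base class for all package errors."""


class ValidationError(StressCCCError, ValueError):
    """Invalid input: bad shapes, out-of-range parameters, broken invariants."""


class UndefinedIndexError(ValidationError):
    """A behavioral index is undefined (e.g. zero exploration denominator)."""


class DegenerateFitError(StressCCCError, ValueError):
    """A model fit is degenerate (e.g. all observations identical for k > 1)."""


class FormatError(StressCCCError, ValueError):
    """A file does not conform to the expected on-disk format."""
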