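"""Exception hierarchy for case-mix validation and estimator preconditions."""


class BedValueError(Exception):
    """Base class for all package-specific errors."""


class MissingInputError(BedValueError):
    """A field required by the requested approach or objective is absent."""


class InvalidContextError(BedValueError):
    """The economic context is unusable (e.g. non-positive threshold)."""


class DegenerateDenominatorError(BedValueError):
    """A ratio's denominator is zero (e.g. treatment-equivalents with C_j = 0)."""


class EmptyCaseMixError(BedValueError):
    """A case mix with no patient groups was supplied."""


class MissingAlternativeError(BedValueError):
    """An approach that needs a forgone alternative was requested but none resolves."""


class CaseMixParseError(BedValueError):
    """A case-mix file violates the expected schema; carries row/field location."""
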