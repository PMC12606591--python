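"""Exception hierarchy for fixelharm.

All package-specific failures derive from :class:`FixelHarmError` so callers
(and the CLI) can distinguish user/data errors from genuine bugs.
"""


class FixelHarmError(Exception):
    """Base class for all fixelharm errors."""


class FormatError(FixelHarmError):
    """A required file is missing or not in the expected format."""


class IntegrityError(FixelHarmError):
    """A fixel template violates its structural invariants."""


class ShapeError(FixelHarmError):
    """An array's dimensions do not match the template or its partner."""


class SchemaError(FixelHarmError):
    """A covariate table is missing required columns."""


class ValidationError(FixelHarmError):
    """Input values violate a precondition (duplicates, batch sizes, ...)."""


class DesignError(FixelHarmError):
    """The regression design matrix is rank deficient."""


class NumericalError(FixelHarmError):
    """A model update produced a non-finite value."""


class UndefinedEffectError(FixelHarmError):
    """An effect size is undefined (zero pooled spread)."""
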