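"""Exception hierarchy for mopkit.

Profile I/O distinguishes three failure modes so callers (and the CLI) can
report them precisely: the file does not match the schema, a value is outside
its legal range, or the pieces of the profile are mutually inconsistent.
"""


class MopkitError(Exception):
    """Base class for all mopkit errors."""


class ProfileSchemaError(MopkitError):
    """The input file does not parse as the documented profile schema."""


class ProfileRangeError(MopkitError, ValueError):
    """A numeric field lies outside its documented range."""


class ProfileConsistencyError(MopkitError, ValueError):
    """Cross-references within a profile do not line up."""


class UnknownInterventionError(MopkitError, KeyError):
    """An intervention id is not present in the profile's catalogue."""


class FamilyPlanningRoutingError(MopkitError, TypeError):
    """The family-planning intervention was passed to the single-intervention
    engine; it must go through :mod:`mopkit.family_planning` instead."""


class DegenerateInputError(MopkitError, ValueError):
    """Inputs drive a model denominator to zero or below."""
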