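"""Exception hierarchy for evdassess.

All domain errors derive from :class:`EVDAssessError` so callers can catch one
base class; input-shape errors additionally derive from ``ValueError``.
"""


class EVDAssessError(Exception):
    """Base class for all evdassess errors."""


class InvalidInputError(EVDAssessError, ValueError):
    """A value violates a documented precondition (non-unit direction, d < 0, ...)."""


class DegenerateProjectionError(EVDAssessError, ValueError):
    """A direction is orthogonal to the requested anatomical plane, so its
    in-plane angle is undefined."""


class ConfigError(EVDAssessError, ValueError):
    """A configuration block (rubric thresholds, cohort config) is invalid."""


class EmptySessionError(EVDAssessError, ValueError):
    """A per-participant operation received no trials."""


class DataIntegrityError(EVDAssessError, ValueError):
    """Input tables violate a structural contract (duplicate participant/pair
    records, unknown schema version, ...)."""


class UnderdeterminedFitError(EVDAssessError, ValueError):
    """A regression was requested with too few distinct predictor values."""
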