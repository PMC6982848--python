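"""Exception hierarchy for stemsurvey.

All domain errors derive from :class:`StemSurveyError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class StemSurveyError(Exception):
    """Base class for all stemsurvey domain errors."""


class InvalidCalibrationError(StemSurveyError):
    """Angle-sensor calibration constants are unusable (nonpositive references)."""


class OutOfRangeStemError(StemSurveyError):
    """Contact angle implies a stem outside the caliper frame's measurable range."""


class MalformedExchangeError(StemSurveyError):
    """Two-way-ranging timestamp exchange violates its timing invariants."""


class ImaginaryProjectionError(StemSurveyError):
    """A slope distance is shorter than the altitude difference it must span."""


class DegenerateGeometryError(StemSurveyError):
    """Anchor layout is collinear or otherwise unusable for trilateration."""


class UndefinedStatisticError(StemSurveyError):
    """A summary statistic was requested on an empty or degenerate sample."""


class CodeParseError(StemSurveyError):
    """A tree-code payload string does not match the TN…|YN… grammar."""


class SchemaError(StemSurveyError):
    """A CSV/config file violates the expected schema."""
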