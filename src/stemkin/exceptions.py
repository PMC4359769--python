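"""Exception hierarchy for stemkin.

Plain ``ValueError`` is raised for bad arguments (negative rates, unsupported
units); the classes below mark failures with domain meaning, so callers can
distinguish "this curve cannot be modeled" from "this file is malformed".
"""


class StemkinError(Exception):
    """Base class for all stemkin-specific errors."""


class FormatError(StemkinError):
    """A data file does not match the expected tabular layout."""


class ScheduleError(StemkinError):
    """A frame schedule violates contiguity/positivity invariants."""


class EmptyCurveError(ScheduleError):
    """An operation (e.g. rebasing) left a curve with no frames."""


class UnfittableCurveError(StemkinError):
    """A time-activity curve carries no usable signal for the requested fit."""


class NoConvergenceError(StemkinError):
    """The trapping-rate solve could not bracket a root.

    Signals a curve inconsistent with irreversible trapping, e.g. observed
    activity still rising steeply at the final-condition time.
    """


class DegenerateFitError(StemkinError):
    """A regression has no spread in its predictor (identical arrival times)."""


class InsufficientDataError(StemkinError):
    """Fewer plants/ROIs than a statistic requires."""


class ReportError(StemkinError):
    """A report cannot be rendered because a required field is missing."""
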