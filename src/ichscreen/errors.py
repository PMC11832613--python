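"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`ICHScreenError` so callers (and the
CLI) can distinguish input problems from internal failures.
"""


class ICHScreenError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(ICHScreenError, ValueError):
    """An operation was configured with an invalid parameter."""


class GeometryError(ICHScreenError):
    """Shapes, dimensions or alignments of inputs disagree."""


class MultiSeriesError(ICHScreenError):
    """A directory mixes DICOM files from more than one series."""


class MetadataError(ICHScreenError):
    """Required DICOM metadata (e.g. rescale tags) is missing."""


class CalibrationError(ICHScreenError):
    """Threshold calibration received degenerate labels."""


class EmptyTIVError(ICHScreenError):
    """No voxel of the volume falls inside the brain-window span."""


class UndefinedMetricError(ICHScreenError):
    """A requested metric has a zero denominator; names the metric."""

    def __init__(self, metric: str):
        self.metric = metric
        super().__init__(f"metric {metric!r} is undefined (zero denominator)")


class AlignmentError(ICHScreenError):
    """Two per-case tables do not cover the same case set."""


class CompletenessError(ICHScreenError):
    """A verdict required for scoring is missing."""


class PhantomSpecError(ICHScreenError, ValueError):
    """A phantom specification violates its own constraints."""


class RatingsParseError(ICHScreenError):
    """A ratings CSV row is malformed; carries the line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")
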