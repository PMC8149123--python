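"""Exception hierarchy for the capdyn pipeline.

Every stage raises a subclass of :class:`CapdynError`, so callers (and the
CLI) can catch one type and exit with a diagnostic.
"""


class CapdynError(Exception):
    """Base class for all capdyn errors."""


class ConfigError(CapdynError):
    """Invalid, unknown, or out-of-range configuration value."""


class FormatError(CapdynError):
    """A file could not be parsed as the expected format."""


class SceneError(CapdynError):
    """A synthetic scene cannot be constructed as requested."""


class ParameterError(CapdynError):
    """An operation parameter violates its documented range."""


class DetectionError(CapdynError):
    """No plane/object satisfied the detection criterion."""


class AlignmentError(CapdynError):
    """A track is too short to be aligned at the requested anchor."""


class NormalizationError(CapdynError):
    """A normalization denominator is zero or negative."""


class ClassificationError(CapdynError):
    """Phase rules produced out-of-order or inconsistent boundaries."""


class FitError(CapdynError):
    """A nonlinear fit failed to converge from every start."""


class MetricError(CapdynError):
    """Derived-metric preconditions violated (e.g. prebleach <= bleach)."""


class DegenerateDataError(CapdynError):
    """A statistic is undefined on the given sample (constant data, n too small)."""
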