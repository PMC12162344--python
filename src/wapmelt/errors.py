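"""Exception hierarchy shared across the toolkit."""


class WapmeltError(Exception):
    """Base class for all toolkit errors."""


class DegenerateEndmemberError(WapmeltError):
    """End-member configuration is singular or too ill-conditioned to invert."""


class InvalidInputError(WapmeltError):
    """Input values are non-finite or violate a documented precondition."""


class CoverageError(WapmeltError):
    """A time series or field does not cover the requested window or period."""


class InsufficientDataError(WapmeltError):
    """Too few observations for the requested statistic."""


class GeometryError(WapmeltError):
    """Region of interest does not overlap the field, or is ill-formed."""


class UndefinedAnomalyError(WapmeltError):
    """Percent anomaly requested against a zero climatological mean."""


class FormatError(WapmeltError):
    """A file does not conform to the expected layout."""


class ConfigError(WapmeltError):
    """Configuration file is invalid or contains unknown keys."""
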