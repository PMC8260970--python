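"""Exception types shared across the pipeline."""


class ThreshcurveError(Exception):
    """Base class for package errors."""


class ConfigurationError(ThreshcurveError):
    """An invalid simulation or pipeline configuration; names the bad field."""


class NoEventsError(ThreshcurveError):
    """A model fit was requested on data with no (or too few) death events."""


class NumericalError(ThreshcurveError):
    """An internal numerical cross-check failed."""
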