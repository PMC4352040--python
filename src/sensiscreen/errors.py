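"""Exception hierarchy shared across the pipeline.

Configuration problems (bad thresholds, malformed matrices, impossible
simulation settings) and data problems (missing controls, degenerate
plates, empty reference lists) are kept distinct so the command line can
map them onto different exit codes.
"""


class SensiscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SensiscreenError, ValueError):
    """Invalid configuration: bad thresholds, matrices, or simulation knobs."""


class DataError(SensiscreenError, ValueError):
    """Invalid or degenerate input data."""


class MissingControlsError(DataError):
    """A plate/condition/replicate group contains no control wells."""


class DegeneratePlateError(DataError):
    """Control wells of a plate have zero spread; Z scores are undefined."""


class PairingError(DataError):
    """Scores from the two backgrounds could not be paired by amplicon."""


class DegenerateChannelError(DataError):
    """A reporter channel has a non-positive total; normalization undefined."""


class UndefinedRateError(DataError):
    """An error rate or fraction was requested over an empty reference set."""
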