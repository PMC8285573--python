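"""Exception hierarchy."""


class LVLoopsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LVLoopsError, ValueError):
    """An argument violates a documented precondition."""


class InconsistentContourError(LVLoopsError):
    """Endocardial/epicardial contours are geometrically incompatible."""


class BeatDetectionError(LVLoopsError):
    """No heartbeats could be identified in a pressure recording."""


class SynchronizationError(LVLoopsError):
    """The end-diastolic landmark of a pressure curve is undetectable."""


class ModelDomainError(LVLoopsError):
    """Inputs fall outside the validity domain of the elastance model."""


class UndefinedStatisticError(LVLoopsError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ConfigError(LVLoopsError):
    """A run configuration is malformed or inconsistent."""


class ParseError(LVLoopsError):
    """An input file violates the exchange-format schema."""
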