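"""Exception hierarchy for the painhrv pipeline."""


class PainHRVError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(PainHRVError, ValueError):
    """A configuration or call parameter is outside its valid range."""


class SimulationError(PainHRVError):
    """The generative model produced a physiologically impossible value
    (e.g. a beat interval below the 300 ms clamp)."""


class NoPeaksError(PainHRVError):
    """R-peak detection found no usable peaks (flat or degenerate trace)."""


class InsufficientDataError(PainHRVError, ValueError):
    """Too few beats/intervals for the requested computation."""


class InvalidDatasetError(PainHRVError, ValueError):
    """A dataset-level contract is violated (empty, single-class,
    single-subject, ...)."""


class ConfigError(PainHRVError, ValueError):
    """A run-configuration file is malformed or contains unknown keys."""
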