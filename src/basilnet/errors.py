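"""Exception hierarchy shared across the package."""


class BasilnetError(Exception):
    """Base class for all package errors."""


class BedFormatError(BasilnetError):
    """The .bed file does not start with the PLINK 1 magic bytes."""


class UnsupportedLayoutError(BedFormatError):
    """The .bed file is sample-major (mode byte 0x00); only variant-major is supported."""


class TruncatedBedError(BedFormatError):
    """The .bed file length disagrees with 3 + n_variants * ceil(n_samples / 4)."""


class AlignmentError(BasilnetError):
    """Sample identifiers or variant universes do not line up between inputs."""


class DegenerateResponseError(BasilnetError):
    """The response carries no usable signal (constant y, single class, no events)."""


class CollinearityError(BasilnetError):
    """The unpenalized design (intercept + covariates) is rank deficient."""


class ConfigError(BasilnetError):
    """Invalid, unknown, or ill-typed configuration value."""


class ConvergenceError(BasilnetError):
    """The solver failed to make progress even after exhausting its fallbacks."""
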