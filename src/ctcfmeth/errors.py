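"""Exception hierarchy shared across the pipeline.

Configuration problems (bad parameters) and data problems (bad files,
degenerate inputs) are kept distinct so the CLI can map them to different
exit codes.
"""


class CtcfMethError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CtcfMethError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(CtcfMethError, ValueError):
    """A file or table violates the expected format."""


class RangeError(FormatError):
    """A methylation value lies outside the admissible [0, 1] range."""


class ConsistencyError(FormatError):
    """Metadata fields contradict each other (e.g. a staged normal sample)."""


class DataError(CtcfMethError, ValueError):
    """Input data are structurally valid but unusable for the requested analysis."""


class EmptyResultError(DataError):
    """A filtering step discarded everything."""


class CalibrationError(DataError):
    """A standard curve or threshold derivation is degenerate."""
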