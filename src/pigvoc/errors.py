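"""Exception hierarchy shared across the package."""


class PigvocError(Exception):
    """Base class for package errors."""


class InvalidInputError(PigvocError, ValueError):
    """Malformed or degenerate numeric input (empty/zero-power/short)."""


class EmptySegmentError(PigvocError, ValueError):
    """Every frame fell below the silence threshold; caller should drop the clip."""


class ConfigurationError(PigvocError, ValueError):
    """Missing tier, inconsistent sizes, or otherwise bad configuration."""


class ParseError(PigvocError, ValueError):
    """A file did not parse in the expected format."""


class SplitInfeasibleError(PigvocError, ValueError):
    """Too few groups to build the requested partition."""


class LeakageError(PigvocError, RuntimeError):
    """A split violates group or pig-wise mutual exclusion."""


class NoValidFramesError(PigvocError, ValueError):
    """All frames are masked out; pooling/attention has nothing to aggregate."""


class CoverageError(PigvocError, ValueError):
    """Out-of-fold predictions do not cover every sample exactly once."""


class ManifestError(PigvocError, ValueError):
    """A dataset manifest is missing required metadata."""


class DivergenceError(PigvocError, RuntimeError):
    """Training produced a non-finite loss."""
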