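"""Exception hierarchy.

Each validation invariant gets its own class so callers (and tests) can tell
apart *which* contract a bad trial or file violates.
"""


class GaitDynError(Exception):
    """Base class for all gaitdyn errors."""


class GaitDataError(GaitDynError, ValueError):
    """A GaitTrial / Cohort invariant is violated."""


class MissingChannelError(GaitDataError):
    """A required kinematic channel is absent."""


class ChannelLengthError(GaitDataError):
    """Channels are present but of unequal length (or empty)."""


class NonFiniteSampleError(GaitDataError):
    """A channel contains NaN or infinite samples."""


class DurationMismatchError(GaitDataError):
    """Sample count disagrees with round(rate * duration)."""


class UnknownGroupError(GaitDataError):
    """Group label is neither ACL_D nor ACL_I."""


class DuplicateSubjectError(GaitDataError):
    """A cohort contains two trials with the same subject id."""


class TrialParseError(GaitDynError, ValueError):
    """A trial file is malformed; message names the offending field/row."""


class CycleDetectionError(GaitDynError, ValueError):
    """No gait cycle could be detected in a trial."""


class EmbeddingError(GaitDynError, ValueError):
    """Series too short (or otherwise unfit) for the requested embedding."""


class NormalizationError(GaitDynError, ValueError):
    """Feature normalizer cannot be fitted (e.g. zero-range column)."""


class IntegrationError(GaitDynError, ArithmeticError):
    """An ODE integration produced a non-finite state."""


class ConfigError(GaitDynError, ValueError):
    """Invalid or unknown pipeline configuration."""
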