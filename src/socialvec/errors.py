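"""Typed exceptions raised across the package."""


class SocialVecError(Exception):
    """Base class for all package errors."""


class ParameterError(SocialVecError, ValueError):
    """An argument is outside its documented domain."""


class InvalidTrajectoryError(SocialVecError):
    """A trajectory cannot be cleaned (e.g. every frame invalid)."""


class EmptyMapError(SocialVecError):
    """A rate map was requested but no valid frame falls inside the grid."""


class ConfigError(SocialVecError):
    """A session bundle or run configuration is incomplete or inconsistent."""


class AlignmentError(SocialVecError):
    """Channels of a session disagree on the number of frames."""


class AnnotationError(SocialVecError):
    """A behavior-annotation interval violates its invariants."""
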