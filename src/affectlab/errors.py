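"""Exception hierarchy.

All package errors derive from :class:`AffectLabError` so callers can catch
one base class at pipeline boundaries.
"""


class AffectLabError(Exception):
    """Base class for all affectlab errors."""


class FormatError(AffectLabError):
    """A file does not conform to the expected on-disk dialect."""


class IntegrityError(AffectLabError):
    """Data is well-formed but violates a contract (rates, ordering, spans)."""


class ConfigurationError(AffectLabError):
    """Invalid parameter values (overlapping segments, non-positive rates...)."""


class UndefinedFeatureError(AffectLabError):
    """A feature cannot be computed for a segment (no samples / no clean epochs).

    Raised instead of silently returning zero so that the pipeline can flag
    the segment explicitly.
    """
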