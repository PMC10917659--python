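"""Exception hierarchy for spectrolaminar.

All package errors derive from :class:`SpectrolaminarError` so callers can
catch everything with one clause while still distinguishing failure modes.
"""


class SpectrolaminarError(Exception):
    """Base class for all spectrolaminar errors."""


class FormatError(SpectrolaminarError):
    """A file or metadata sidecar is malformed or missing a required field."""


class ValidationError(SpectrolaminarError):
    """Input data violate an invariant (non-finite voltage, bad shapes...)."""


class BoundsError(SpectrolaminarError):
    """A requested window or band falls outside the recorded axis."""


class ResolutionError(SpectrolaminarError):
    """The analysis window is too short for the requested frequency grid."""


class QualityError(SpectrolaminarError):
    """Data quality too poor to analyse (e.g. too many bad channels)."""


class NormalizationError(SpectrolaminarError):
    """Normalization undefined (all-zero frequency column, single trial...)."""


class ParameterError(SpectrolaminarError):
    """An analysis parameter is out of its legal range."""


class SpanError(SpectrolaminarError):
    """Too few channels for the requested depth-range search."""


class NoCrossoverError(SpectrolaminarError):
    """No alpha-beta/gamma crossover exists inside the selected range."""


class ShapeError(SpectrolaminarError):
    """Two maps have incompatible dimensions; standardize them first."""


class SizeError(SpectrolaminarError):
    """A probe group is too small for the requested subdivision."""
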