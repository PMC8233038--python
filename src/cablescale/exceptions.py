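"""Exception hierarchy.

All package errors derive from :class:`CableScaleError` so callers can catch
everything with one clause; each also derives from the closest builtin
(ValueError / RuntimeError) so generic handling keeps working.
"""


class CableScaleError(Exception):
    """Base class for all cablescale errors."""


class ValidationError(CableScaleError, ValueError):
    """Invalid input data or parameter values."""


class ConfigurationError(CableScaleError, ValueError):
    """Unknown family, missing parameter, or inconsistent configuration."""


class UnsupportedFamilyError(ConfigurationError):
    """Operation undefined for the requested feedback family."""


class IntegrationError(CableScaleError, RuntimeError):
    """Numerical integration became unstable or violated an invariant."""


class EstimationError(CableScaleError, RuntimeError):
    """A fit failed to converge or had too few observations."""


class DegenerateFitError(EstimationError):
    """Fit is undefined (e.g. zero variance in the predictor)."""
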