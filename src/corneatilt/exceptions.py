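"""Exception hierarchy shared across the package."""


class CorneaTiltError(Exception):
    """Base class for all package-specific errors."""


class OutOfDomainError(CorneaTiltError, ValueError):
    """A surface was evaluated where its sagitta is not real."""


class ApertureError(CorneaTiltError, ValueError):
    """A fitted surface was evaluated outside its fitted aperture."""


class FitError(CorneaTiltError, ValueError):
    """Surface fitting failed (too few points or rank deficiency)."""


class TotalInternalReflectionError(CorneaTiltError, ValueError):
    """Snell refraction has no real transmitted ray (sin(theta_t) > 1)."""


class RayTraceError(CorneaTiltError, RuntimeError):
    """A ray missed a surface or a trace could not be completed."""


class GsuValidationError(CorneaTiltError, ValueError):
    """Densitometry values outside the standardised greyscale range [0, 100]."""


class CohortCsvError(CorneaTiltError, ValueError):
    """A cohort table is malformed (missing column or non-numeric cell)."""
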