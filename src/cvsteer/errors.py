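"""Exception hierarchy shared across the package."""


class CvsteerError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(CvsteerError):
    """Raised when a CV is evaluated on geometry where it is undefined
    (e.g. a dihedral with collinear bond vectors)."""


class ConfigurationError(CvsteerError):
    """Raised for invalid run configurations, CV sets or model parameters."""


class IntegrationError(CvsteerError):
    """Raised when dynamics blow up (non-finite energy/forces or runaway
    coordinates). Carries the step index and, when available, the partial
    trajectory recorded so far."""

    def __init__(self, message, step=None, partial=None):
        super().__init__(message)
        self.step = step
        self.partial = partial


class FormatError(CvsteerError):
    """Raised for malformed structure, series or config files."""
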