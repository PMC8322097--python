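"""Exception hierarchy for scampi."""


class ScampiError(Exception):
    """Base class for all scampi errors."""


class InvalidImageError(ScampiError):
    """Image is empty, non-finite, or otherwise unusable."""


class EmptyDesignError(ScampiError):
    """Lag order leaves no interior pixels to regress on."""


class CollinearityError(ScampiError):
    """Design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class InsufficientSamplesError(ScampiError):
    """Fewer observations than parameters."""


class DegenerateClassesError(ScampiError):
    """Class means coincide; no discriminating direction exists."""


class DegenerateDataError(ScampiError):
    """Zero-variance or otherwise degenerate sample."""


class StabilityError(ScampiError):
    """Requested lag coefficients violate the stability advisory."""
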