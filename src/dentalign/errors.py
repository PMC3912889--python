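"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class DentalignError(Exception):
    """Base class for all errors raised by this package."""


class MeshFormatError(DentalignError):
    """Malformed or truncated STL input; message names the byte/line offset."""


class DegenerateGeometryError(DentalignError):
    """Zero-area one-ring, isolated vertex, collinear frame points, etc."""


class SelectionError(DentalignError):
    """Reference-point selection impossible (too few or collinear features)."""


class NoMatchError(DentalignError):
    """No candidate triple satisfies the distance/area constraints.

    Carries ``best_residuals`` — the smallest combined normalized residual
    seen among distinct candidate triples — to help threshold diagnosis.
    """

    def __init__(self, message, best_residuals=None):
        super().__init__(message)
        self.best_residuals = best_residuals


class EstimationError(DentalignError):
    """Rigid-transform estimation failed (too few pairs, rank deficiency)."""


class PhantomError(DentalignError):
    """Synthetic pair generation produced an unregistrable configuration."""
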