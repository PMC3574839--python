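"""Error types raised across the package."""


class TcmixError(Exception):
    """Base class for package errors."""


class InvalidParameterError(TcmixError, ValueError):
    """A model or algorithm parameter is outside its admissible range."""


class SingularCovarianceError(TcmixError):
    """A component covariance matrix is singular (all variance terms zero)."""


class DegenerateComponentError(TcmixError):
    """A mixture component lost essentially all responsibility mass."""

    def __init__(self, component: int, mass: float):
        self.component = component
        self.mass = mass
        super().__init__(
            f"component {component} is degenerate (responsibility mass {mass:.3g})"
        )


class NumericalError(TcmixError):
    """A numerical failure (non-finite objective, failed factorisation)."""


class ConfigurationError(TcmixError, ValueError):
    """An invalid simulation or run configuration."""


class NormalizationError(TcmixError):
    """Degenerate input to row/column standardisation (zero variance)."""
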