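"""Exception hierarchy shared across the package."""


class OrbitempoError(Exception):
    """Base class for all orbitempo errors."""


class ParameterError(OrbitempoError, ValueError):
    """A biochemical rate is missing, non-positive, or non-finite."""


class SchemaError(OrbitempoError, ValueError):
    """A parameter file or table does not match the documented schema."""


class DomainError(OrbitempoError, ValueError):
    """An input leaves the mathematical domain of an operation
    (e.g. a prefactor evaluating to a non-positive value)."""


class IntegrationError(OrbitempoError, RuntimeError):
    """The ODE solver failed or produced non-finite states."""


class NonConvergenceError(OrbitempoError, RuntimeError):
    """A trajectory did not settle onto a steady state in the allotted time."""


class NotOscillatoryError(OrbitempoError, RuntimeError):
    """Limit-cycle extraction found too few Poincare-section crossings."""


class DegenerateOrbitError(OrbitempoError, ValueError):
    """An orbit has zero arc length and cannot be resampled."""


class ConfigError(OrbitempoError, ValueError):
    """A run configuration file is invalid."""


class UnsupportedModelError(OrbitempoError, TypeError):
    """The model lacks the declared structure required by an operation
    (e.g. no prefactor decomposition)."""


class CalibrationWarning(UserWarning):
    """A shipped parameter set failed a qualitative sanity check
    (e.g. expected cascade or bistability not observed)."""
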