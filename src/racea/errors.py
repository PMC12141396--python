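"""Exception hierarchy shared across the package."""


class RaceaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RaceaError):
    """A configuration value is missing, of the wrong type, or out of range."""


class DomainError(RaceaError):
    """An input value lies outside the mathematical domain of an operation."""


class GenerationError(RaceaError):
    """A synthetic record cannot be generated consistently with its constraints."""


class DegenerateDataError(RaceaError):
    """Statistical routine received data with no variation to analyse."""


class SeparationError(RaceaError):
    """Logistic model cannot be fitted because the arms are perfectly separable."""


class CollinearityError(RaceaError):
    """Design matrix is rank deficient; a covariate is redundant."""


class DependencyError(RaceaError):
    """A pipeline stage was requested before the stage it depends on."""
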