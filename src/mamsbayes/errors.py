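"""Exception hierarchy for mamsbayes."""


class MamsError(Exception):
    """Base class for all mamsbayes errors."""


class InvalidParameterError(MamsError, ValueError):
    """A numeric argument is outside its admissible range."""


class ConfigurationError(MamsError, ValueError):
    """A trial configuration is inconsistent (e.g. zero or two control arms)."""


class IntegrationError(MamsError, RuntimeError):
    """Numerical integration failed to reach the requested tolerance.

    Attributes
    ----------
    achieved : float
        The absolute-error estimate actually achieved by the integrator.
    requested : float
        The tolerance that was requested.
    """

    def __init__(self, message: str, achieved: float, requested: float):
        super().__init__(message)
        self.achieved = achieved
        self.requested = requested


class LogParseError(MamsError, ValueError):
    """An enrollment log is malformed; the message names the offending record."""
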