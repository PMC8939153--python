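"""Exception hierarchy for the simulator.

All validation failures raise :class:`InputValidationError` (a ``ValueError``)
so callers can catch one type for bad user input; configuration-level
inconsistencies (e.g. an unsolvable muscle equilibrium) raise
:class:`ConfigurationError`.
"""


class MyoarmError(Exception):
    """Base class for all package errors."""


class InputValidationError(MyoarmError, ValueError):
    """An argument violated a documented precondition."""


class ConfigurationError(MyoarmError):
    """A configuration is internally inconsistent or unsolvable."""


class CalibrationError(ConfigurationError):
    """An EMG calibration is degenerate (e.g. MVC not above baseline)."""


class NumericalError(MyoarmError):
    """The integrator produced a non-finite state component."""
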