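"""Exception hierarchy."""


class LumistraddleError(Exception):
    """Base class for all package errors."""


class ParameterError(LumistraddleError, ValueError):
    """A model or configuration parameter violates its invariants."""


class InputError(LumistraddleError, ValueError):
    """Invalid user-supplied data (shapes, ordering, ranges)."""


class TimingError(LumistraddleError, ValueError):
    """Inconsistent acquisition timing (pulse/exposure/interframe)."""


class TimingMismatchError(TimingError):
    """Calibration and measurement were acquired with different timing.

    The apparent Stern-Volmer constant depends on pulse length and
    interframe time, so inverting a P_N image with a calibration taken at
    different timing silently biases the O2 map. Raised unless the caller
    explicitly forces the inversion.
    """


class CalibrationError(LumistraddleError, ValueError):
    """Calibration data cannot be fitted (too few / degenerate levels)."""


class NumericsError(LumistraddleError, ArithmeticError):
    """A numerical routine (quadrature, fit) failed to converge."""
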