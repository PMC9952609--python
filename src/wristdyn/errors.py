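"""Exception hierarchy for wristdyn."""


class WristdynError(Exception):
    """Base class for all wristdyn errors."""


class ParameterError(WristdynError, ValueError):
    """A model or configuration parameter is invalid or missing."""


class InputError(WristdynError, ValueError):
    """Input data violates a precondition (shape, length, finiteness)."""


class IdentifiabilityError(WristdynError, ValueError):
    """The identification design matrix is rank deficient.

    Carries the deficient direction(s) in joint-displacement space so the
    caller knows which excitation is missing.
    """

    def __init__(self, message, deficient_directions=None):
        super().__init__(message)
        self.deficient_directions = deficient_directions


class NumericalError(WristdynError, RuntimeError):
    """A numerical procedure failed (singular matrix, divergence)."""


class UndefinedFeatureError(WristdynError, ValueError):
    """A spectral feature is undefined for the given spectrum (zero power)."""


class UndefinedRatioError(WristdynError, ZeroDivisionError):
    """A torque ratio has a zero denominator."""


class NotFittedError(WristdynError, RuntimeError):
    """A model was used before being fitted."""
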