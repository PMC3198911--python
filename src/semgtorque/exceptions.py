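"""Exception and warning types shared across the package."""


class SemgTorqueError(ValueError):
    """Base class for all package errors."""


class InvalidInputError(SemgTorqueError):
    """Malformed or inconsistent data (wrong shapes, missing channels, ...)."""


class InvalidParameterError(SemgTorqueError):
    """A configuration or model parameter outside its admissible range."""


class UndefinedMetricError(SemgTorqueError):
    """A metric whose denominator or degrees of freedom are degenerate."""


class DegenerateChannelWarning(UserWarning):
    """An SEMG channel carries no signal (identically zero)."""
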