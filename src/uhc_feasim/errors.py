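"""Exception hierarchy shared across the pipeline stages."""


class FeasimError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FeasimError, ValueError):
    """An argument violates a precondition (negative horizon, rate < 0, ...)."""


class DegenerateInputError(FeasimError, ZeroDivisionError):
    """A ratio was requested against a zero denominator (no visits, no funds)."""


class ConfigurationError(FeasimError, ValueError):
    """A scenario, service, or input file is unknown, malformed, or incomplete."""
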