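"""Exception hierarchy for oabayes."""


class OabayesError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OabayesError, ValueError):
    """A protocol, noise spec, or parameter set violates its invariants."""


class InputError(OabayesError, ValueError):
    """An input object (trace, schedule, table) is malformed or inconsistent."""


class NumericalError(OabayesError, ArithmeticError):
    """A numerical routine produced a non-finite or unstable result."""


class OracleResolutionError(OabayesError, ValueError):
    """The brute-force grid is too coarse to resolve the posterior."""


class FittingError(OabayesError, RuntimeError):
    """A statistical fit failed or did not converge."""
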