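"""Exception and warning types shared across the package."""


class MucopairError(Exception):
    """Base class for all package errors."""


class ValidationError(MucopairError):
    """Invalid configuration, metadata, or input table."""


class DegenerateDataError(MucopairError):
    """Input data carries no usable signal (zero variance, empty, all filtered)."""


class ConvergenceWarning(UserWarning):
    """An MCMC chain set failed the PSRF convergence gate (R-hat > threshold)."""
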