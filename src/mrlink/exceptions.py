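"""Exception hierarchy for mrlink.

All package-specific failures derive from :class:`MrLinkError` so callers
(and the CLI) can distinguish configuration problems, empty analytic
results and genuinely broken inputs from programming errors.
"""


class MrLinkError(Exception):
    """Base class for all mrlink errors."""


class ConfigurationError(MrLinkError):
    """A config file, dialect map or parameter set is invalid."""


class EmptyInputError(MrLinkError):
    """An input file contained no usable rows."""


class EmptyResultError(MrLinkError):
    """A filter or intersection removed every SNP.

    Callers decide whether this is fatal; the CLI maps it to exit code 3.
    """


class InsufficientInstrumentsError(MrLinkError):
    """An estimator was called with fewer instruments than it requires."""


class UndefinedRatioError(MrLinkError):
    """Wald ratio requested with a zero exposure effect."""


class UndefinedProportionError(MrLinkError):
    """Proportion mediated requested with a zero total effect."""


class SingularDesignError(MrLinkError):
    """Multivariable regression design matrix is rank deficient."""
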