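"""Exception hierarchy shared across the package."""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError):
    """A column mapping, config file, or parameter set is invalid."""


class EmptyInputError(TsmrError):
    """An operation received (or produced) zero usable records."""


class EmptyInstrumentError(TsmrError):
    """Instrument selection exhausted every candidate SNP.

    ``step`` names the first filter that emptied the set.
    """

    def __init__(self, step: str, message: str | None = None):
        self.step = step
        super().__init__(message or f"no instruments remain after step '{step}'")


class InsufficientInstrumentsError(TsmrError):
    """Fewer SNPs than the estimator's minimum."""


class DegenerateInstrumentError(TsmrError):
    """An instrument has a zero exposure effect where a ratio is required."""


class CollinearityError(TsmrError):
    """The multivariable exposure-effect matrix is rank deficient."""


class LassoDegenerateError(TsmrError):
    """No lasso penalty yields a usable valid instrument set."""


class UndefinedProportionError(TsmrError):
    """Mediated proportion requested with a zero total effect."""


class MissingLDError(TsmrError):
    """A SNP required for clumping is absent from the LD matrix."""
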