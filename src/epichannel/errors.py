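"""Exception hierarchy shared across the package.

All data-contract violations raise subclasses of :class:`EpichannelError`
so callers (the CLI in particular) can report stage context without
catching bare ``ValueError``.
"""


class EpichannelError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EpichannelError):
    """Input file does not follow the expected schema (missing columns...)."""


class ValidationError(EpichannelError):
    """A value violates a domain invariant (negative count, bad week...)."""


class DiseaseNotFoundError(EpichannelError, KeyError):
    """Requested disease label absent from the input."""


class IncompleteBaselineError(EpichannelError):
    """A baseline week has too few observations to form a channel."""


class DegenerateInputError(EpichannelError):
    """A statistical routine received an input with no variability."""


class UndefinedChangeError(EpichannelError):
    """Percent change undefined because the baseline median is zero."""
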