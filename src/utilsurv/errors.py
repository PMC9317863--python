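"""Exception types raised across the package."""


class UtilsurvError(Exception):
    """Base class for all package-specific errors."""


class FormatError(UtilsurvError):
    """Input file does not match the expected tabular layout."""


class ContiguityError(UtilsurvError):
    """A monthly series has a gap between its first and last month."""


class InsufficientHistoryError(UtilsurvError):
    """Too few usable historical points to build a reference design."""


class FitError(UtilsurvError):
    """The baseline regression could not be estimated."""


class NotConvergedError(UtilsurvError):
    """An operation requires a converged fit but the fit did not converge."""
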