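"""Exception hierarchy shared across the package.

Two broad classes matter for the command line: validation/parse problems
(exit code 2) and degenerate data that cannot be quantified (exit code 3).
"""


class ImprintscanError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ImprintscanError):
    """Invalid configuration, malformed input, or contract violation."""

    exit_code = 2


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending field/row."""


class AmbiguousPeakError(ValidationError):
    """A peak size falls inside the window of more than one amplicon."""


class DuplicateRunError(ValidationError):
    """Two runs of the same condition for one sample; no silent averaging."""


class IncompleteScreenError(ValidationError):
    """A sample is missing the measurement for one or more panel loci."""


class ChromosomeMismatchError(ValidationError):
    """A UPD verdict was applied to a locus on a different chromosome."""


class DegenerateDataError(ImprintscanError):
    """Data that cannot be quantified (all-zero denominators and the like)."""

    exit_code = 3


class BaselineError(DegenerateDataError):
    """The control baseline is unusable (too few controls, zero mean, ...)."""
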