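"""Exception hierarchy shared across the pipeline."""


class ConnstabError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ConnstabError, ValueError):
    """A parameter violates its precondition."""


class DegenerateInputError(ConnstabError, ValueError):
    """Input is structurally valid but statistically degenerate
    (zero variance, unrepairable covariance, collapsed distribution)."""


class InvalidDesignError(ConnstabError, ValueError):
    """The group/condition design cannot support the requested analysis
    (empty cell, too few subjects, fewer observations than cells)."""


class FormatError(ConnstabError, ValueError):
    """An on-disk dataset violates the expected layout; message names the
    offending file and field."""
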