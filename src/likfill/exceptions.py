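"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI lives in :mod:`likfill.cli`.
"""


class LikfillError(Exception):
    """Base class for all package errors."""


class ValidationError(LikfillError):
    """Input violated a structural invariant (duplicate id, missing field...)."""


class FormatError(LikfillError):
    """A file could not be parsed under the declared format."""


class InfeasibleError(LikfillError):
    """No gap-filling solution exists in the merged network."""


class GapfillTimeoutError(LikfillError):
    """The MILP solver exhausted the maximum allowed time."""


class UnboundedError(LikfillError):
    """An LP objective is unbounded (open flux cycle through the objective)."""
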