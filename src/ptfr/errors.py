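"""Exception hierarchy for :mod:`ptfr`.

Everything raised deliberately by the package derives from :class:`PtfrError`
so callers (and the CLI) can separate data problems from genuine bugs.
"""

from __future__ import annotations


class PtfrError(ValueError):
    """Base class for all errors raised by ptfr."""


class SchemaError(PtfrError):
    """A required column is missing or a file dialect cannot be resolved."""


class RowValidationError(PtfrError):
    """A single input row violates an invariant.

    Carries the 0-based data row index (header excluded) so the offending
    line is easy to locate in the source file.
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class UndefinedRateError(PtfrError):
    """A follow-up rate was requested for an empty cohort or tau <= 0."""


class OracleMissingError(PtfrError):
    """The true person-time rate needs an event time (or a never-event
    marker) for every dropout, and at least one is absent."""


class ConvergenceWarning(UserWarning):
    """The NPMLE self-consistency iteration stopped at max_iter."""
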