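"""Exception hierarchy.

All package errors derive from :class:`AaiScoreError`; most also derive from
``ValueError`` so callers who do not care about the distinction can catch the
builtin.
"""


class AaiScoreError(Exception):
    """Base class for all errors raised by this package."""


class InputValidationError(AaiScoreError, ValueError):
    """A value violates an input contract (non-finite, out of range, bad schema)."""


class InsufficientDataError(AaiScoreError, ValueError):
    """Too few usable observations for the requested computation."""


class DegenerateDesignError(AaiScoreError, ValueError):
    """The design matrix is degenerate (e.g. a single distinct dose)."""


class MissingDataError(AaiScoreError, ValueError):
    """A required group x analyte cell (or reference/calibrator record) is absent."""


class UndefinedInverseError(AaiScoreError, ZeroDivisionError):
    """The reciprocal of a zero slope was requested."""
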