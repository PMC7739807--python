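"""Exception hierarchy shared across the pipeline."""


class RunloadError(Exception):
    """Base class for all runload-specific errors."""


class InvalidFilterError(RunloadError, ValueError):
    """Filter specification incompatible with the trace (e.g. cutoff >= Nyquist)."""


class TooShortError(RunloadError, ValueError):
    """Trace or interval too short for the requested operation."""


class UnitError(RunloadError, ValueError):
    """Trace carries the wrong physical units for the operation."""


class UndefinedCorrelationError(RunloadError, ValueError):
    """Correlation undefined because an input has zero variance."""


class EmptySessionError(RunloadError, ValueError):
    """A session-level statistic was requested on an empty step stream."""


class GroupingError(RunloadError, ValueError):
    """Records that must share a grouping key (runner id) do not."""


class CollinearityError(RunloadError, ValueError):
    """Design matrix is rank deficient."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class DegenerateSplitError(RunloadError, ValueError):
    """A cross-validation split would leave an empty training set."""


class DataError(RunloadError, ValueError):
    """Malformed or inconsistent input data."""
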