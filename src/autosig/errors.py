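"""Exception hierarchy for the autosig pipeline.

Every stage raises a subclass of :class:`AutosigError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class AutosigError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AutosigError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(AutosigError):
    """Unparseable input file (bad lineage, empty table, wrong layout)."""


class DataError(AutosigError):
    """Structurally valid input with invalid content (e.g. negative counts)."""


class DuplicateTaxonError(DataError):
    """Two rows/columns collapse to the same canonical lineage."""


class DuplicateSampleError(DataError):
    """Sample identifiers collide (within or across merged studies)."""


class IncompatibleProfilesError(AutosigError):
    """Profiles cannot be combined (e.g. counts merged with relative)."""


class InsufficientDataError(AutosigError):
    """Too few samples per class to proceed."""


class EmptyProfileError(AutosigError):
    """Every sample was removed by a filtering step."""


class EmptyFeatureError(AutosigError):
    """Every feature was removed by a filtering step."""


class DimensionError(AutosigError):
    """Mismatched sample sets or matrix shapes."""


class GroupingError(AutosigError):
    """A grouping vector is degenerate (e.g. a single group for PERMANOVA)."""


class EvaluationError(AutosigError):
    """A held-out evaluation cannot be computed (e.g. single-class test set)."""


class ConsistencyError(AutosigError):
    """Inputs that must agree do not (e.g. rank maps over different taxa)."""
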