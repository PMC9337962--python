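"""Exception hierarchy for physfit.

Every error raised deliberately by the package derives from
:class:`PhysfitError`, so callers can catch package failures with a single
``except`` clause while still distinguishing the failure mode by subclass.
"""


class PhysfitError(Exception):
    """Base class for all physfit errors."""


class CohortFormatError(PhysfitError):
    """A cohort file is structurally unreadable (missing id/sex column, not CSV)."""


class CohortValidationError(PhysfitError):
    """Cohort content violates an invariant (duplicate subject ids, bad sex code)."""


class ImputationError(PhysfitError):
    """Attribute-mean imputation is impossible (an indicator has no observed value)."""


class MissingScoreError(PhysfitError):
    """An indicator was scored before its measurement was imputed."""


class DatasetError(PhysfitError):
    """A labeled dataset is empty or an attribute/class lookup failed."""


class TreeInputError(PhysfitError):
    """A row handed to ``classify`` lacks an attribute the tree tests."""


class DegenerateWindowError(PhysfitError):
    """Windowed training requires at least two classes in the data."""


class MatrixValidationError(PhysfitError):
    """A judgment matrix is not square, positive, unit-diagonal and reciprocal."""


class UnsupportedOrderError(PhysfitError):
    """Judgment-matrix order falls outside the random-index table (1-9)."""


class UndefinedMetricError(PhysfitError):
    """A comparison metric is undefined for this input (e.g. single-class labels)."""


class ConfigurationError(PhysfitError):
    """Hierarchy, rule table or tree configuration is inconsistent."""
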