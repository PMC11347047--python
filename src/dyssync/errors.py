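"""Exception hierarchy for the dyssync package."""


class DyssyncError(Exception):
    """Base class for all dyssync errors."""


class CohortFormatError(DyssyncError, ValueError):
    """A cohort file violates the documented on-disk format."""


class IncompleteGridError(CohortFormatError):
    """A subject's curve grid is missing one or more (kind, segment) cells."""


class CohortJoinError(CohortFormatError):
    """Curves and subject records do not join one-to-one on subject_id."""


class CurveDataError(DyssyncError, ValueError):
    """A deformation curve contains invalid (e.g. non-finite) samples."""


class DegenerateCurveError(CurveDataError):
    """A curve is flat to within tolerance; peaks and delays are undefined."""


class InsufficientDataError(DyssyncError, ValueError):
    """Too few segments/slices/values to evaluate a metric."""


class ConstantFeatureError(DyssyncError, ValueError):
    """A feature column has zero variance and cannot be z-scored."""


class ProjectionError(DyssyncError, ValueError):
    """PCA projection is not defined for the given input."""


class DegenerateClusteringError(DyssyncError, RuntimeError):
    """K-means could not produce a valid partition."""


class ZeroEventsError(DyssyncError, ValueError):
    """No events observed; the log-rank statistic is undefined."""


class CoxFitError(DyssyncError, RuntimeError):
    """Cox partial-likelihood maximization failed (e.g. collinear design)."""
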