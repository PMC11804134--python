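"""Exception hierarchy shared across the package.

Every error a caller may want to branch on derives from :class:`MetsRiskError`.
"""


class MetsRiskError(Exception):
    """Base class for all package errors."""


class ConfigError(MetsRiskError):
    """A model or study configuration is malformed or incomplete."""


class ConsistencyError(ConfigError):
    """A configuration violates an internal invariant (e.g. a partial-model
    variant declaring lipid predictors)."""


class InputError(MetsRiskError, ValueError):
    """Numeric or tabular input outside its domain (non-finite values,
    mismatched lengths, thresholds outside (0, 1), ...)."""


class MissingPredictorError(MetsRiskError, KeyError):
    """A record does not supply a value for a predictor the model declares.

    Deliberately loud: the caller decides whether to impute, never the
    prediction routine.
    """


class UnknownDrugError(MetsRiskError, KeyError):
    """An antipsychotic name absent from the metabolic-activity lookup.

    Unknown drugs are never silently assigned a class.
    """


class UndefinedMetricError(MetsRiskError):
    """A performance metric is undefined for the supplied data
    (e.g. C-statistic with a single outcome class)."""


class DegenerateFitError(MetsRiskError):
    """A model fit is degenerate: constant design column, perfect separation,
    exactly collinear predictors."""


class ConvergenceError(MetsRiskError):
    """An iterative fit failed to converge; carries any diagnostics the
    optimiser produced."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnstableCIError(MetsRiskError):
    """The bootstrap statistic was undefined in too many replicates for a
    percentile interval to be trusted."""


class CannotImputeError(MetsRiskError):
    """Imputation is impossible (a field is 100% missing, or no fully
    observed field exists to anchor the chained equations)."""


class FeasibilityError(MetsRiskError):
    """Conditional simulation could not satisfy a constraint within the
    retry budget; the message names the constraint."""


class AnalysisError(MetsRiskError):
    """An analysis callback failed on one or more imputed datasets; carries
    the failing imputation indices."""

    def __init__(self, message, indices=None):
        super().__init__(message)
        self.indices = tuple(indices or ())
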