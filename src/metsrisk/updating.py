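"""Site-specific model updating: recalibration and penalised re-estimation.

The standard updating hierarchy for transported prediction models:

1. *intercept update* — re-estimate only the intercept (calibration-in-the-
   large), fitting the outcome on an offset equal to the linear predictor;
2. *logistic calibration* — re-estimate intercept and a single slope
   multiplier on the linear predictor, assuming similar relative effects of
   the predictors but allowing a larger or smaller absolute effect;
3. *full refit* — re-estimate every coefficient by ridge-penalised logistic
   regression on the template's predictor set, optionally substituting a
   predictor (here: country of birth replacing ethnicity, which is how a
   site-specific variant is built when the development model's ethnicity
   coding does not transport).

Ridge rather than LASSO because the predictor set is forced-entry (no
selection wanted) and an ~15-event cohort needs heavy shrinkage rather than
sparsity.  Standard errors for the penalised fit come from the inverse
penalised Hessian at the solution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .errors import ConvergenceError, DegenerateFitError, InputError
from .metrics import calibration_fit
from .risk_model import PredictorSpec, RiskModel

__all__ = ["UpdateResult", "recalibrate", "refit_site_specific"]

logger = logging.getLogger(__name__)


@dataclass
class UpdateResult:
    """Outcome of one updating step: the new model plus fit diagnostics."""

    method: str  # {"intercept_update", "logistic_calibration", "full_refit"}
    updated_model: RiskModel
    fitted_parameters: dict[str, tuple[float, float]]  # name -> (estimate, se)
    convergence: dict

    def __post_init__(self):
        if self.updated_model.site != "site_specific":
            raise InputError("updated models must carry site='site_specific'")


def _design_and_lp(model: RiskModel, cohort: pd.DataFrame):
    lp = model.linear_predictor_frame(cohort)
    return np.asarray(lp, dtype=float)


def _check_outcomes(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise InputError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise InputError("both outcome classes required")
    return y


def recalibrate(
    model: RiskModel,
    cohort: pd.DataFrame,
    outcomes: Sequence[float],
    method: str = "logistic_calibration",
) -> UpdateResult:
    """Recalibrate a risk model on local validation data.

    ``intercept_update`` shifts only the intercept by the offset-fit estimate
    â, correcting calibration-in-the-large.  ``logistic_calibration`` fits
    observed outcomes on the linear predictor (intercept b0, slope b1) and
    composes the update into the coefficients: every coefficient is scaled
    by b1 and the intercept becomes b0 + b1·intercept, so the updated
    model's linear predictor is exactly b0 + b1·LP.  Either way the rank
    ordering of predictions — hence discrimination — is unchanged.
    """
    y = _check_outcomes(outcomes)
    lp = _design_and_lp(model, cohort)
    if method == "intercept_update":
        fit = calibration_fit(lp, y, mode="intercept_only")
        updated = replace(
            model,
            name=f"{model.name}_intercept_updated",
            site="site_specific",
            intercept=model.intercept + fit.intercept,
            provenance=f"intercept update of {model.name}",
        )
        params = {"delta_intercept": (fit.intercept, fit.intercept_se)}
        diagnostics = {"mode": "offset_fit"}
    elif method == "logistic_calibration":
        fit = calibration_fit(lp, y, mode="intercept_slope")
        b0, b1 = fit.intercept, fit.slope
        new_predictors = tuple(
            replace(p, coefficient=b1 * p.coefficient) for p in model.predictors
        )
        updated = RiskModel(
            name=f"{model.name}_recalibrated",
            variant=model.variant,
            site="site_specific",
            intercept=b0 + b1 * model.intercept,
            predictors=new_predictors,
            provenance=f"logistic calibration of {model.name}",
        )
        params = {
            "calibration_intercept": (b0, fit.intercept_se),
            "calibration_slope": (b1, fit.slope_se),
        }
        diagnostics = {"mode": "two_parameter_logistic"}
    else:
        raise InputError(f"unknown recalibration method {method!r}")
    return UpdateResult(
        method=method,
        updated_model=updated,
        fitted_parameters=params,
        convergence=diagnostics,
    )


def _apply_swap(
    template: RiskModel, swap: Optional[Mapping[str, str | PredictorSpec]]
) -> tuple[PredictorSpec, ...]:
    if not swap:
        return template.predictors
    specs = []
    names = set(template.predictor_names)
    for old, new in swap.items():
        if old not in names:
            raise InputError(f"swap source {old!r} not in template predictors")
    for p in template.predictors:
        if p.name in swap:
            new = swap[p.name]
            if isinstance(new, PredictorSpec):
                specs.append(new)
            else:
                # same kind/encoding shape, new field; coefficient refit anyway
                specs.append(replace(p, name=str(new)))
        else:
            specs.append(p)
    return tuple(specs)


def refit_site_specific(
    template: RiskModel,
    cohort: pd.DataFrame,
    outcomes: Sequence[float],
    swap: Optional[Mapping[str, str | PredictorSpec]] = None,
    penalty: Optional[float] = None,
    cv_folds: int = 5,
    seed: int = 0,
    name: Optional[str] = None,
) -> UpdateResult:
    """Re-estimate every coefficient of ``template`` on local data.

    ``swap`` maps a template predictor name to its replacement (e.g.
    ``{"ethnicity": "born_in_australia"}``).  ``penalty`` is the ridge
    strength λ on the coefficients (intercept unpenalised); ``None`` selects
    it by seeded, outcome-stratified cross-validation.  When events number
    fewer than predictors the fit proceeds under heavy shrinkage with a
    logged warning — the realistic small-validation-cohort situation.
    """
    y = _check_outcomes(outcomes)
    specs = _apply_swap(template, swap)

    X = np.column_stack(
        [
            np.array([s.encode(v) for v in cohort[s.name]], dtype=float)
            if s.name in cohort.columns
            else _raise_missing(s.name)
            for s in specs
        ]
    )
    n, k = X.shape
    events = int(y.sum())
    for j, s in enumerate(specs):
        if np.ptp(X[:, j]) == 0:
            raise DegenerateFitError(
                f"swapped-in or template predictor {s.name!r} is constant in the cohort"
            )
    if events < k:
        logger.warning(
            "refit with %d events and %d predictors: estimates rely on shrinkage",
            events,
            k,
        )

    if penalty is None:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        est = LogisticRegressionCV(
            Cs=np.logspace(-3, 3, 13),
            cv=cv,
            scoring="neg_log_loss",
            max_iter=5000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(X, y)
            chosen_C = float(np.atleast_1d(est.C_)[0])
    else:
        if penalty <= 0:
            raise InputError("ridge penalty must be positive")
        chosen_C = 1.0 / penalty
        est = LogisticRegression(C=chosen_C, max_iter=5000)
        est.fit(X, y)

    coefs = est.coef_.ravel().astype(float)
    intercept = float(est.intercept_[0])

    # penalised-Hessian standard errors: H = X̃'WX̃ + λ·diag(0,1,...,1)
    lam = 1.0 / chosen_C
    Xt = np.column_stack([np.ones(n), X])
    p = expit(Xt @ np.concatenate([[intercept], coefs]))
    W = p * (1 - p)
    H = (Xt * W[:, None]).T @ Xt
    H[1:, 1:] += lam * np.eye(k)
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:  # pragma: no cover
        ses = np.full(k + 1, np.nan)

    new_predictors = tuple(
        replace(s, coefficient=float(c)) for s, c in zip(specs, coefs)
    )
    updated = RiskModel(
        name=name or f"{template.name}_site_specific",
        variant=template.variant,
        site="site_specific",
        intercept=intercept,
        predictors=new_predictors,
        provenance=(
            f"ridge refit (lambda={lam:.4g}) of {template.name} on local data"
            + (f"; swapped {dict(swap)}" if swap else "")
        ),
    )
    params = {"intercept": (intercept, float(ses[0]))}
    for s, c, se in zip(new_predictors, coefs, ses[1:]):
        params[s.name] = (float(c), float(se))
    return UpdateResult(
        method="full_refit",
        updated_model=updated,
        fitted_parameters=params,
        convergence={
            "ridge_lambda": lam,
            "n": n,
            "events": events,
            "n_predictors": k,
            "n_iter": int(np.max(est.n_iter_)),
        },
    )


def _raise_missing(name: str):
    from .errors import MissingPredictorError

    raise MissingPredictorError(name)
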