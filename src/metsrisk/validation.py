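"""Model-object front end: fit-and-summarise external validation and updating.

``ExternalValidation`` pairs a published risk model with local cohort data;
``.fit()`` computes the validation panel (C-statistic, Nagelkerke R², Brier
score, calibration intercept and slope, grouped calibration) with
stratified-bootstrap confidence intervals and returns a
:class:`ValidationResults` carrying the estimates, the decile table, a
``summary()`` string, decision-curve and calibration-plot helpers.

``ModelUpdate`` does the same for the updating hierarchy (intercept update,
logistic calibration, penalised full refit with optional predictor swap):
``.fit()`` returns an :class:`UpdateResults` whose ``updated_model`` can be
validated or serialised straight back to the config format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import dca as _dca
from . import metrics as _metrics
from .cohort import IDFCutoffs, ParticipantRecord, analysis_frame
from .errors import InputError
from .risk_model import RiskModel
from .updating import UpdateResult, recalibrate, refit_site_specific

__all__ = ["ExternalValidation", "ValidationResults", "ModelUpdate", "UpdateResults"]


def _resolve_outcome(data: pd.DataFrame, outcome) -> tuple[pd.DataFrame, np.ndarray]:
    if isinstance(outcome, str):
        if outcome not in data.columns:
            raise InputError(f"outcome column {outcome!r} not in data")
        y = data[outcome].to_numpy(dtype=float)
        X = data.drop(columns=[outcome])
    else:
        y = np.asarray(outcome, dtype=float)
        X = data
    if len(y) != len(X):
        raise InputError("outcome length must match data")
    if np.isnan(y).any():
        raise InputError("outcome contains missing values; filter or impute first")
    return X, y


class ExternalValidation:
    """External validation of a fixed risk equation on a local cohort.

    Parameters
    ----------
    model
        The risk equation under validation (its coefficients are *not*
        re-estimated here).
    data
        Cohort table with one row per participant supplying every model
        predictor (raw levels or encoded design values).
    outcome
        Binary outcome column name in ``data`` or an aligned array.
    """

    def __init__(self, model: RiskModel, data: pd.DataFrame, outcome="outcome"):
        self.model = model
        self.data, self.outcomes = _resolve_outcome(data, outcome)
        pred = model.predict_frame(self.data)
        self.linear_predictors = pred["linear_predictor"].to_numpy()
        self.risks = pred["risk"].to_numpy()

    @classmethod
    def from_records(
        cls,
        model: RiskModel,
        records: Sequence[ParticipantRecord],
        cutoffs: IDFCutoffs = IDFCutoffs(),
    ) -> "ExternalValidation":
        frame = analysis_frame(records, cutoffs=cutoffs).drop(columns=["id"])
        return cls(model, frame, outcome="outcome")

    def fit(
        self, bootstrap_replicates: int = 2000, seed: int = 0, groups: int = 10
    ) -> "ValidationResults":
        report = _metrics.compute_validation_report(
            self.risks,
            self.linear_predictors,
            self.outcomes,
            bootstrap_replicates=bootstrap_replicates,
            seed=seed,
            groups=groups,
        )
        return ValidationResults(self, report)


@dataclass
class ValidationResults:
    """Estimates, intervals and diagnostics from one external validation."""

    model_obj: ExternalValidation
    report: _metrics.ValidationReport

    @property
    def risks(self):
        return self.model_obj.risks

    @property
    def outcomes(self):
        return self.model_obj.outcomes

    @property
    def calibration_table(self) -> pd.DataFrame:
        return _metrics.deciles_to_frame(self.report.decile_table)

    def decision_curve(
        self, thresholds=None, bootstrap: Optional[_dca.BootstrapSpec] = None
    ) -> _dca.DecisionCurve:
        return _dca.decision_curve(
            self.risks, self.outcomes, thresholds=thresholds, bootstrap=bootstrap
        )

    def summary(self) -> str:
        r = self.report
        m = self.model_obj.model
        lines = [
            "External validation results",
            "=" * 60,
            f"model:       {m.name} ({m.variant}, {m.site})",
            f"n:           {r.n}    events: {r.n_events} "
            f"(prevalence {r.n_events / r.n:.3f})",
            "-" * 60,
            f"{'metric':<22}{'estimate':>10}{'95% CI':>22}",
        ]
        labels = {
            "c_statistic": "C-statistic",
            "r2_nagelkerke": "Nagelkerke R2",
            "brier": "Brier score",
            "cal_intercept": "calibration intercept",
            "cal_slope": "calibration slope",
        }
        for key, label in labels.items():
            est = getattr(r, key)
            lines.append(
                f"{label:<22}{est.estimate:>10.3f}"
                f"{'(' + format(est.ci_low, '.3f') + ', ' + format(est.ci_high, '.3f') + ')':>22}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    def plot_calibration(self, ax=None):
        """Observed vs predicted risk: decile triangles with Wilson CIs plus
        the logistic calibration curve and the identity line."""
        import matplotlib.pyplot as plt
        from scipy.special import expit

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        table = self.calibration_table
        ax.errorbar(
            table["mean_predicted"],
            table["observed_proportion"],
            yerr=[
                table["observed_proportion"] - table["ci_low"],
                table["ci_high"] - table["observed_proportion"],
            ],
            fmt="^",
            color="black",
            capsize=2,
            label="deciles of predicted risk",
        )
        lims = [0, max(0.05, float(table[["mean_predicted", "ci_high"]].max().max()) * 1.05)]
        ax.plot(lims, lims, color="red", lw=1, label="perfect calibration")
        grid = np.linspace(1e-4, max(self.risks.max(), lims[1]), 200)
        logit_grid = np.log(grid / (1 - grid))
        cal = expit(
            self.report.cal_intercept.estimate
            + self.report.cal_slope.estimate * logit_grid
        )
        ax.plot(grid, cal, color="black", lw=1.5, label="calibration fit")
        ax.set_xlabel("predicted risk")
        ax.set_ylabel("observed proportion")
        ax.legend(loc="upper left", fontsize=8)
        return ax


class ModelUpdate:
    """Site-specific updating of a risk model on local data.

    ``method`` is one of ``intercept_update``, ``logistic_calibration`` or
    ``full_refit`` (the three-level updating hierarchy); ``swap`` applies a
    predictor substitution during a full refit.
    """

    def __init__(
        self,
        model: RiskModel,
        data: pd.DataFrame,
        outcome="outcome",
        method: str = "logistic_calibration",
        swap: Optional[Mapping[str, str]] = None,
        penalty: Optional[float] = None,
        seed: int = 0,
    ):
        self.model = model
        self.data, self.outcomes = _resolve_outcome(data, outcome)
        self.method = method
        self.swap = dict(swap) if swap else None
        self.penalty = penalty
        self.seed = seed

    def fit(self) -> "UpdateResults":
        if self.method in ("intercept_update", "logistic_calibration"):
            result = recalibrate(self.model, self.data, self.outcomes, self.method)
        elif self.method == "full_refit":
            result = refit_site_specific(
                self.model,
                self.data,
                self.outcomes,
                swap=self.swap,
                penalty=self.penalty,
                seed=self.seed,
            )
        else:
            raise InputError(f"unknown updating method {self.method!r}")
        return UpdateResults(self, result)


@dataclass
class UpdateResults:
    """Fitted updating step: parameters, diagnostics, and the updated model."""

    model_obj: ModelUpdate
    result: UpdateResult

    @property
    def updated_model(self) -> RiskModel:
        return self.result.updated_model

    @property
    def fitted_parameters(self):
        return self.result.fitted_parameters

    def validate(self, bootstrap_replicates: int = 2000, seed: int = 0) -> ValidationResults:
        """Re-validate the updated model on the updating data (apparent
        performance; optimism-prone by construction)."""
        ev = ExternalValidation(
            self.updated_model,
            self.model_obj.data,
            outcome=self.model_obj.outcomes,
        )
        return ev.fit(bootstrap_replicates=bootstrap_replicates, seed=seed)

    def summary(self) -> str:
        res = self.result
        lines = [
            "Model updating results",
            "=" * 60,
            f"method:       {res.method}",
            f"source model: {self.model_obj.model.name}",
            f"updated:      {res.updated_model.name} (site_specific)",
            "-" * 60,
            f"{'parameter':<26}{'estimate':>12}{'std err':>12}",
        ]
        for name, (est, se) in res.fitted_parameters.items():
            lines.append(f"{name:<26}{est:>12.4f}{se:>12.4f}")
        for key, value in res.convergence.items():
            lines.append(f"  {key}: {value}")
        lines.append("=" * 60)
        return "\n".join(lines)
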