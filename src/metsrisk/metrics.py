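"""Discrimination, calibration and overall-performance statistics.

The vocabulary is the standard external-validation toolkit for clinical
prediction models: the concordance (C-) statistic, the Nagelkerke
(Cox–Snell rescaled) R², the Brier score, logistic calibration intercept
and slope, grouped calibration at deciles of predicted risk, stratified
bootstrap confidence intervals, and the variance inflation factor.

Conventions
-----------
* The calibration *intercept* is reported from the slope-fixed offset fit
  (outcome regressed on an offset equal to the linear predictor); the
  calibration *slope* from the two-parameter logistic refit.  A positive
  validation intercept means the model under-predicts risk.
* Decile bins are formed by a stable sort of predicted risk with earlier
  bins absorbing remainders; bin proportions get Wilson 95% intervals,
  which behave at the per-bin n ≈ 12 of a 116-person cohort.
* Bootstrap resampling is stratified by outcome so every replicate keeps
  the observed event count — at 13% prevalence unstratified resampling
  produces event-free replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    ConvergenceError,
    DegenerateFitError,
    InputError,
    UndefinedMetricError,
    UnstableCIError,
)

__all__ = [
    "c_statistic",
    "brier_score",
    "nagelkerke_r2",
    "calibration_fit",
    "CalibrationFit",
    "calibration_deciles",
    "DecileBin",
    "bootstrap_ci",
    "vif",
    "CollinearityReport",
    "ValidationReport",
    "compute_validation_report",
]


def _as_arrays(risks, outcomes):
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if r.shape != y.shape or r.ndim != 1:
        raise InputError(
            f"risks and outcomes must be aligned 1-d arrays, got {r.shape} vs {y.shape}"
        )
    if r.size == 0:
        raise InputError("empty input")
    if not np.all(np.isfinite(r)):
        raise InputError("non-finite risks")
    if not np.all((y == 0) | (y == 1)):
        raise InputError("outcomes must be binary 0/1")
    return r, y


def c_statistic(risks: Sequence[float], outcomes: Sequence[float]) -> float:
    """Concordance statistic with the half-credit tie correction.

    Equals (concordant pairs + 0.5·tied pairs) / all case–non-case pairs,
    computed in O(n log n) via midranks: with R the sum of case ranks and
    n1 cases, C = (R − n1(n1+1)/2) / (n1·n0).
    """
    r, y = _as_arrays(risks, outcomes)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError(
            "C-statistic undefined: need at least one case and one non-case"
        )
    ranks = rankdata(r, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def brier_score(risks: Sequence[float], outcomes: Sequence[float]) -> float:
    """Mean squared difference between predicted probability and outcome."""
    r, y = _as_arrays(risks, outcomes)
    return float(np.mean((r - y) ** 2))


def nagelkerke_r2(risks: Sequence[float], outcomes: Sequence[float]) -> float:
    """Cox–Snell likelihood-ratio R² rescaled to a [0, 1] maximum.

    Cox–Snell R² = 1 − (L0/L1)^(2/n) where L1 is the Bernoulli likelihood of
    the supplied risks and L0 that of the constant-prevalence model; the
    Nagelkerke rescaling divides by its maximum 1 − L0^(2/n).
    """
    r, y = _as_arrays(risks, outcomes)
    prevalence = y.mean()
    if prevalence in (0.0, 1.0):
        raise UndefinedMetricError("both outcome classes required")
    degenerate = ((r == 0) & (y == 1)) | ((r == 1) & (y == 0))
    if degenerate.any():
        raise DegenerateFitError(
            "risk exactly 0 or 1 with a discordant outcome: likelihood is zero"
        )
    n = len(y)
    ll1 = float(np.sum(y * np.log(np.clip(r, 1e-300, 1)) +
                       (1 - y) * np.log(np.clip(1 - r, 1e-300, 1))))
    ll0 = float(n * (prevalence * math.log(prevalence) +
                     (1 - prevalence) * math.log(1 - prevalence)))
    cox_snell = 1.0 - math.exp((2.0 / n) * (ll0 - ll1))
    max_cs = 1.0 - math.exp((2.0 / n) * ll0)
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


@dataclass(frozen=True)
class CalibrationFit:
    """Calibration intercept and slope with standard errors.

    Unpacks as ``(intercept, slope)``.
    """

    intercept: float
    slope: float
    intercept_se: float = float("nan")
    slope_se: float = float("nan")
    mode: str = "intercept_slope"

    def __iter__(self):
        return iter((self.intercept, self.slope))


def calibration_fit(
    linear_predictors: Sequence[float],
    outcomes: Sequence[float],
    mode: str = "intercept_slope",
) -> CalibrationFit:
    """Maximum-likelihood logistic calibration of outcomes on the linear predictor.

    ``intercept_only`` fixes the slope at 1 (the linear predictor enters as
    an offset) and estimates the calibration-in-the-large intercept — the
    convention under which the reported calibration intercept is defined.
    ``intercept_slope`` estimates both parameters; its slope is the reported
    calibration slope.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if lp.shape != y.shape or lp.ndim != 1:
        raise InputError("linear predictors and outcomes must be aligned 1-d arrays")
    if not np.all(np.isfinite(lp)):
        raise InputError("non-finite linear predictors")
    if y.min() == y.max():
        raise UndefinedMetricError("both outcome classes required")
    if mode not in ("intercept_only", "intercept_slope"):
        raise InputError(f"unknown calibration mode {mode!r}")

    if mode == "intercept_only":
        model = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp)
        try:
            res = model.fit()
        except PerfectSeparationError as exc:  # pragma: no cover - tiny-n corner
            raise ConvergenceError("perfect separation in offset fit") from exc
        return CalibrationFit(
            intercept=float(res.params[0]),
            slope=1.0,
            intercept_se=float(res.bse[0]),
            slope_se=0.0,
            mode=mode,
        )

    if np.ptp(lp) == 0:
        raise DegenerateFitError(
            "constant linear predictor: calibration slope undefined"
        )
    design = sm.add_constant(lp)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        except (PerfectSeparationError, RuntimeWarning) as exc:
            raise ConvergenceError(
                "logistic calibration failed to converge (separation?)",
                diagnostics={"n": len(y), "events": int(y.sum())},
            ) from exc
    if not res.converged or np.abs(res.params).max() > 1e4:
        raise ConvergenceError(
            "logistic calibration failed to converge",
            diagnostics={"params": res.params.tolist()},
        )
    return CalibrationFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        mode=mode,
    )


@dataclass(frozen=True)
class DecileBin:
    """One grouped-calibration bin: predicted vs observed with a Wilson CI."""

    bin_index: int
    n: int
    mean_predicted: float
    observed_proportion: float
    ci_low: float
    ci_high: float


def calibration_deciles(
    risks: Sequence[float], outcomes: Sequence[float], groups: int = 10
) -> list[DecileBin]:
    """Grouped observed vs predicted risk at quantiles of predicted risk.

    Stable sort by predicted risk; the first ``n mod groups`` bins take one
    extra member so sizes are near-equal and deterministic under ties.
    """
    r, y = _as_arrays(risks, outcomes)
    n = len(r)
    if n < groups:
        raise InputError(f"need at least {groups} observations, got {n}")
    order = np.argsort(r, kind="stable")
    base, rem = divmod(n, groups)
    bins: list[DecileBin] = []
    start = 0
    for b in range(groups):
        size = base + (1 if b < rem else 0)
        idx = order[start : start + size]
        start += size
        events = int(y[idx].sum())
        obs = events / size
        lo, hi = proportion_confint(events, size, alpha=0.05, method="wilson")
        bins.append(
            DecileBin(
                bin_index=b + 1,
                n=size,
                mean_predicted=float(r[idx].mean()),
                observed_proportion=float(obs),
                ci_low=float(lo),
                ci_high=float(hi),
            )
        )
    return bins


def deciles_to_frame(bins: Sequence[DecileBin]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in bins])


def _stratified_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx_case = np.flatnonzero(y == 1)
    idx_ctrl = np.flatnonzero(y == 0)
    return np.concatenate(
        [
            rng.choice(idx_case, size=idx_case.size, replace=True),
            rng.choice(idx_ctrl, size=idx_ctrl.size, replace=True),
        ]
    )


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    risks: Sequence[float],
    outcomes: Sequence[float],
    replicates: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI with outcome-stratified case resampling.

    Stratification preserves the event count in every replicate.  If the
    statistic is undefined in more than 10% of replicates the interval is
    refused (:class:`UnstableCIError`).
    """
    r, y = _as_arrays(risks, outcomes)
    if replicates < 100:
        raise InputError("need at least 100 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(replicates):
        idx = _stratified_indices(y, rng)
        try:
            values.append(statistic(r[idx], y[idx]))
        except Exception:
            failures += 1
    if failures > 0.10 * replicates:
        raise UnstableCIError(
            f"statistic undefined in {failures}/{replicates} replicates"
        )
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def bootstrap_se(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    risks: Sequence[float],
    outcomes: Sequence[float],
    replicates: int = 500,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap standard error (stratified), for Rubin pooling of metrics."""
    r, y = _as_arrays(risks, outcomes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = []
    for _ in range(replicates):
        idx = _stratified_indices(y, rng)
        try:
            values.append(statistic(r[idx], y[idx]))
        except Exception:
            continue
    if len(values) < replicates * 0.9:
        raise UnstableCIError("statistic undefined in >10% of replicates")
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# collinearity


@dataclass(frozen=True)
class CollinearityReport:
    """Per-predictor variance inflation factors (inf marks exact collinearity)."""

    vif: dict[str, float]

    @property
    def max_vif(self) -> float:
        return max(self.vif.values())


def vif(design: pd.DataFrame | np.ndarray) -> CollinearityReport:
    """Variance inflation factor 1/(1−R²ⱼ) for each design column.

    R²ⱼ comes from an OLS regression (with constant) of column j on the
    remaining columns.  An exactly collinear column yields ``inf``.
    """
    X = pd.DataFrame(design)
    if X.shape[1] < 2:
        raise InputError("VIF needs at least two columns")
    if X.shape[0] <= X.shape[1]:
        raise InputError("VIF needs more rows than columns")
    names = [str(c) for c in X.columns]
    values = X.to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        yj = values[:, j]
        others = np.delete(values, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            raise DegenerateFitError(f"column {name!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return CollinearityReport(vif=out)


# ---------------------------------------------------------------------------
# assembled report


@dataclass
class MetricEstimate:
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def as_tuple(self):
        return (self.estimate, self.ci_low, self.ci_high)


@dataclass
class ValidationReport:
    """Discrimination, calibration and overall performance for one model/cohort."""

    c_statistic: MetricEstimate
    r2_nagelkerke: MetricEstimate
    brier: MetricEstimate
    cal_intercept: MetricEstimate
    cal_slope: MetricEstimate
    decile_table: list[DecileBin]
    n: int
    n_events: int

    def __post_init__(self):
        if self.n_events > self.n:
            raise InputError("n_events cannot exceed n")
        if self.decile_table and sum(b.n for b in self.decile_table) != self.n:
            raise InputError("decile bin sizes must sum to n")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("c_statistic", "r2_nagelkerke", "brier", "cal_intercept", "cal_slope"):
            m: MetricEstimate = getattr(self, name)
            rows.append(
                {"metric": name, "estimate": m.estimate, "ci_low": m.ci_low, "ci_high": m.ci_high}
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {
            name: dict(zip(("estimate", "ci_low", "ci_high"), getattr(self, name).as_tuple()))
            for name in ("c_statistic", "r2_nagelkerke", "brier", "cal_intercept", "cal_slope")
        }
        d["n"] = self.n
        d["n_events"] = self.n_events
        d["decile_table"] = [vars(b) for b in self.decile_table]
        return d

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def compute_validation_report(
    risks: Sequence[float],
    linear_predictors: Sequence[float],
    outcomes: Sequence[float],
    bootstrap_replicates: int = 2000,
    seed: int = 0,
    groups: int = 10,
) -> ValidationReport:
    """Full external-validation panel with stratified-bootstrap 95% CIs."""
    r, y = _as_arrays(risks, outcomes)
    lp = np.asarray(linear_predictors, dtype=float)

    def stat_c(rr, yy):
        return c_statistic(rr, yy)

    def stat_r2(rr, yy):
        return nagelkerke_r2(rr, yy)

    def stat_brier(rr, yy):
        return brier_score(rr, yy)

    rng = np.random.default_rng(seed)
    cal_int = calibration_fit(lp, y, mode="intercept_only")
    cal_slope = calibration_fit(lp, y, mode="intercept_slope")

    def stat_cal_int(lps, yy):
        return calibration_fit(lps, yy, mode="intercept_only").intercept

    def stat_cal_slope(lps, yy):
        return calibration_fit(lps, yy, mode="intercept_slope").slope

    report = ValidationReport(
        c_statistic=MetricEstimate(
            c_statistic(r, y), *bootstrap_ci(stat_c, r, y, bootstrap_replicates, rng)
        ),
        r2_nagelkerke=MetricEstimate(
            nagelkerke_r2(r, y), *bootstrap_ci(stat_r2, r, y, bootstrap_replicates, rng)
        ),
        brier=MetricEstimate(
            brier_score(r, y), *bootstrap_ci(stat_brier, r, y, bootstrap_replicates, rng)
        ),
        cal_intercept=MetricEstimate(
            cal_int.intercept,
            *bootstrap_ci(stat_cal_int, lp, y, bootstrap_replicates, rng),
        ),
        cal_slope=MetricEstimate(
            cal_slope.slope,
            *bootstrap_ci(stat_cal_slope, lp, y, bootstrap_replicates, rng),
        ),
        decile_table=calibration_deciles(r, y, groups=groups),
        n=len(y),
        n_events=int(y.sum()),
    )
    return report
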