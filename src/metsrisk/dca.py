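"""Decision curve analysis: net benefit across clinically feasible thresholds.

Net benefit at risk threshold t weighs true against false positives by the
threshold odds:

    NB(t) = TP/n − (FP/n) · t/(1−t)

where TP and FP count events and non-events among participants whose
predicted risk is at or above t ("intervene").  The comparators are
treat-all, NB = π − (1−π)·t/(1−t) with π the outcome prevalence, and
treat-none, NB ≡ 0.  A curve below zero marks net harm — more false than
true positives exposed to the intervention at that threshold.

The default grid runs from 0.01 to 0.30 in steps of 0.01: a risk above
roughly one-in-three would not be tolerated without intervention, so larger
thresholds are not clinically meaningful here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedMetricError

__all__ = [
    "net_benefit",
    "net_benefit_treat_all",
    "decision_curve",
    "DecisionCurve",
    "BootstrapSpec",
    "interpret_net_benefit",
    "default_threshold_grid",
]


def default_threshold_grid(upper: float = 0.30, step: float = 0.01) -> np.ndarray:
    """Thresholds (0, upper] at the given step (default 0.01–0.30)."""
    grid = np.round(np.arange(step, upper + step / 2, step), 10)
    return grid[(grid > 0) & (grid < 1)]


def _check(risks, outcomes):
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if r.ndim != 1 or r.shape != y.shape or r.size == 0:
        raise InputError("risks and outcomes must be aligned non-empty 1-d arrays")
    if not np.all((y == 0) | (y == 1)):
        raise InputError("outcomes must be binary 0/1")
    return r, y


def net_benefit(risks: Sequence[float], outcomes: Sequence[float], threshold: float) -> float:
    """Net benefit of intervening at predicted risk ≥ threshold (inclusive)."""
    if not (0 < threshold < 1):
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    r, y = _check(risks, outcomes)
    n = len(y)
    treat = r >= threshold
    tp = float(y[treat].sum())
    fp = float(treat.sum() - tp)
    return tp / n - (fp / n) * threshold / (1.0 - threshold)


def net_benefit_treat_all(prevalence: float, threshold: float) -> float:
    """Closed-form net benefit of intervening in everyone."""
    if not (0 < threshold < 1):
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    return prevalence - (1.0 - prevalence) * threshold / (1.0 - threshold)


@dataclass(frozen=True)
class BootstrapSpec:
    replicates: int = 500
    seed: int = 0


@dataclass
class DecisionCurve:
    """Net benefit of the model and both trivial strategies on a threshold grid."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    n: int
    prevalence: float
    nb_ci_low: Optional[np.ndarray] = None
    nb_ci_high: Optional[np.ndarray] = None

    #: treat-none has zero net benefit at every threshold by definition
    @property
    def nb_treat_none(self) -> np.ndarray:
        return np.zeros_like(self.thresholds)

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if np.any(t <= 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
            raise InputError("thresholds must be strictly increasing within (0, 1)")

    def at(self, threshold: float) -> dict:
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        if not np.isclose(self.thresholds[i], threshold):
            raise InputError(f"threshold {threshold} not on the grid")
        out = {
            "threshold": float(self.thresholds[i]),
            "nb_model": float(self.nb_model[i]),
            "nb_treat_all": float(self.nb_treat_all[i]),
            "nb_treat_none": 0.0,
        }
        if self.nb_ci_low is not None:
            out["nb_ci_low"] = float(self.nb_ci_low[i])
            out["nb_ci_high"] = float(self.nb_ci_high[i])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: (threshold, strategy, net_benefit, ci_low, ci_high)."""
        rows = []
        for i, t in enumerate(self.thresholds):
            rows.append(
                {
                    "threshold": float(t),
                    "strategy": "model",
                    "net_benefit": float(self.nb_model[i]),
                    "ci_low": float(self.nb_ci_low[i]) if self.nb_ci_low is not None else np.nan,
                    "ci_high": float(self.nb_ci_high[i]) if self.nb_ci_high is not None else np.nan,
                }
            )
            rows.append(
                {
                    "threshold": float(t),
                    "strategy": "treat_all",
                    "net_benefit": float(self.nb_treat_all[i]),
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
            rows.append(
                {
                    "threshold": float(t),
                    "strategy": "treat_none",
                    "net_benefit": 0.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def decision_curve(
    risks: Sequence[float],
    outcomes: Sequence[float],
    thresholds: Optional[Sequence[float]] = None,
    bootstrap: Optional[BootstrapSpec] = None,
) -> DecisionCurve:
    """Net benefit of model-guided intervention across a threshold grid.

    Bootstrap CIs (optional) resample participants once per replicate,
    stratified by outcome, and evaluate the whole grid on that resample so
    the band is coherent across thresholds.
    """
    r, y = _check(risks, outcomes)
    t = np.asarray(thresholds if thresholds is not None else default_threshold_grid(),
                   dtype=float)
    prevalence = float(y.mean())
    nb = np.array([net_benefit(r, y, ti) for ti in t])
    nb_all = np.array([net_benefit_treat_all(prevalence, ti) for ti in t])
    lo = hi = None
    if bootstrap is not None:
        rng = np.random.default_rng(bootstrap.seed)
        idx_case = np.flatnonzero(y == 1)
        idx_ctrl = np.flatnonzero(y == 0)
        reps = np.empty((bootstrap.replicates, len(t)))
        for b in range(bootstrap.replicates):
            idx = np.concatenate(
                [
                    rng.choice(idx_case, idx_case.size, replace=True),
                    rng.choice(idx_ctrl, idx_ctrl.size, replace=True),
                ]
            )
            rb, yb = r[idx], y[idx]
            reps[b] = [net_benefit(rb, yb, ti) for ti in t]
        lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return DecisionCurve(
        thresholds=t,
        nb_model=nb,
        nb_treat_all=nb_all,
        n=len(y),
        prevalence=prevalence,
        nb_ci_low=lo,
        nb_ci_high=hi,
    )


def interpret_net_benefit(nb_delta: float, per: int = 100, prevalence: float | None = None) -> dict:
    """Translate a net-benefit difference into cases detected per ``per`` people.

    A net-benefit advantage of Δ means Δ·per additional true positives per
    ``per`` people at no increase in false positives; given the outcome
    prevalence this is also Δ/π of all cases.
    """
    if not np.isfinite(nb_delta):
        raise InputError("net-benefit difference must be finite")
    out = {
        "nb_delta": float(nb_delta),
        "per": int(per),
        "additional_true_positives": float(nb_delta * per),
        "statement": (
            f"{nb_delta * per:.1f} additional true positives per {per} people, "
            "at no increase in false positives"
        ),
    }
    if prevalence is not None:
        if prevalence == 0:
            raise UndefinedMetricError("share of cases undefined at zero prevalence")
        out["share_of_cases"] = float(nb_delta / prevalence)
    return out
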