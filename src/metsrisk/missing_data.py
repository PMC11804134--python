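"""Multiple imputation by chained equations and Rubin's-rules pooling.

Imputation is delegated to statsmodels' ``MICEData`` (chained equations
with predictive-mean matching, default k = 5 donors — PMM keeps imputed
biochemistry inside the observed range and returns observed 0/1 values for
binary fields).  This module wraps it to produce ``m`` *independent* seeded
chains, each burnt in for a fixed number of sweeps, and to make the whole
set reproducible from one integer seed.

Scalar estimates computed on each completed dataset are combined with
Rubin's rules: pooled estimate = mean, total variance = within + (1+1/m)·
between, and a t-based interval on the Rubin (optionally Barnard–Rubin
small-sample adjusted) degrees of freedom.  Bounded statistics such as the
C-statistic should be pooled on the logit scale (`pool_transformed`) so the
back-transformed interval respects the bounds.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from statsmodels.imputation.mice import MICEData

from .errors import AnalysisError, CannotImputeError, InputError

__all__ = [
    "ImputedCohortSet",
    "PooledEstimate",
    "impute_chained",
    "pool_rubin",
    "pool_transformed",
    "per_imputation_outputs",
    "PerImputationResults",
]


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage 31-bit seed derived from a master seed and a label."""
    digest = hashlib.blake2s(f"{master}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class ImputedCohortSet:
    """m completed copies of a cohort table plus provenance metadata."""

    imputations: list[pd.DataFrame]
    m: int
    iterations: int
    seed: int
    missingness_map: dict[str, float]

    def __post_init__(self):
        if len(self.imputations) != self.m:
            raise InputError("number of tables must equal m")

    def to_directory(self, path: str | Path) -> Path:
        """Write per-imputation CSVs plus a JSON manifest."""
        import json

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.imputations):
            df.to_csv(path / f"imputation_{i:02d}.csv", index=False)
        (path / "manifest.json").write_text(
            json.dumps(
                {
                    "m": self.m,
                    "iterations": self.iterations,
                    "seed": self.seed,
                    "missingness_map": self.missingness_map,
                },
                indent=2,
            )
        )
        return path


def impute_chained(
    cohort: pd.DataFrame,
    m: int = 10,
    iterations: int = 10,
    seed: int = 0,
    k_pmm: int = 5,
) -> ImputedCohortSet:
    """Fill missing cells by chained equations (predictive-mean matching).

    Runs ``m`` independent chains, each initialised from ``seed`` and burnt
    in for ``iterations`` sweeps over the incomplete columns.  Non-numeric
    columns must be complete (they are carried through untouched); numeric
    columns may contain NaN.  Deterministic given (data, m, iterations,
    seed).  A column with no observed values cannot be imputed.
    """
    if m < 1 or iterations < 1:
        raise InputError("m and iterations must be positive")
    df = cohort.reset_index(drop=True)
    numeric = df.select_dtypes(include=[np.number, bool]).columns.tolist()
    non_numeric = [c for c in df.columns if c not in numeric]
    for c in non_numeric:
        if df[c].isna().any():
            raise CannotImputeError(
                f"non-numeric column {c!r} contains missing values"
            )
    missing_frac = {c: float(df[c].isna().mean()) for c in df.columns}
    fully_missing = [c for c, f in missing_frac.items() if f >= 1.0]
    if fully_missing:
        raise CannotImputeError(f"columns 100% missing: {fully_missing}")
    if all(f > 0 for f in (missing_frac[c] for c in numeric)) and numeric:
        raise CannotImputeError("chained equations need at least one fully observed field")

    incomplete = [c for c in numeric if missing_frac[c] > 0]
    if not incomplete:
        return ImputedCohortSet(
            imputations=[df.copy() for _ in range(m)],
            m=m,
            iterations=iterations,
            seed=seed,
            missingness_map=missing_frac,
        )

    work = df[numeric].astype(float)
    tables: list[pd.DataFrame] = []
    state = np.random.get_state()
    try:
        for chain in range(m):
            # MICEData draws from the numpy global RandomState
            np.random.seed(derive_seed(seed, f"mice_chain_{chain}"))
            md = MICEData(work.copy(), perturbation_method="gaussian", k_pmm=k_pmm)
            md.update_all(iterations)
            completed = md.data.copy()
            out = df.copy()
            for c in incomplete:  # complete columns keep their dtype
                out[c] = completed[c].to_numpy()
            tables.append(out)
    finally:
        np.random.set_state(state)

    # observed cells must be untouched in every chain
    observed = ~df[numeric].isna()
    for t in tables:
        for c in numeric:
            obs = observed[c].to_numpy()
            if not np.allclose(
                t[c].to_numpy()[obs], df[c].to_numpy(dtype=float)[obs], equal_nan=False
            ):
                raise AnalysisError(f"imputation modified observed cells in {c!r}")
    return ImputedCohortSet(
        imputations=tables,
        m=m,
        iterations=iterations,
        seed=seed,
        missingness_map=missing_frac,
    )


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m repeated-imputation estimates."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    ci_low: float
    ci_high: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def pool_rubin(
    estimates: Sequence[float],
    variances: Sequence[float],
    df_com: Optional[float] = None,
    alpha: float = 0.05,
) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules.

    total variance T = W̄ + (1 + 1/m)·B with W̄ the mean within-imputation
    variance and B the between-imputation sample variance.  Degrees of
    freedom are the classical Rubin value, or the Barnard–Rubin small-sample
    adjustment when the complete-data degrees of freedom ``df_com`` are
    supplied.  ``m = 1`` passes the single estimate through with a warning.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size == 0:
        raise InputError("no estimates to pool")
    if q.shape != u.shape:
        raise InputError("estimates and variances must align")
    if np.any(u < 0):
        raise InputError("variances must be non-negative")
    m = q.size
    if m == 1:
        warnings.warn("pooling a single imputation is degenerate", stacklevel=2)
        se = float(np.sqrt(u[0]))
        z = stats.norm.ppf(1 - alpha / 2)
        return PooledEstimate(
            estimate=float(q[0]),
            within_var=float(u[0]),
            between_var=0.0,
            total_var=float(u[0]),
            ci_low=float(q[0] - z * se),
            ci_high=float(q[0] + z * se),
            df=float("inf"),
            m=1,
        )
    qbar = float(q.mean())
    wbar = float(u.mean())
    b = float(q.var(ddof=1))
    t = wbar + (1 + 1 / m) * b
    if b == 0 or t == 0:
        df = float("inf")
        crit = stats.norm.ppf(1 - alpha / 2)
    else:
        r = (1 + 1 / m) * b / wbar if wbar > 0 else np.inf
        df_old = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else float(m - 1)
        if df_com is not None:
            lam = (1 + 1 / m) * b / t
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
        crit = stats.t.ppf(1 - alpha / 2, df)
    se = np.sqrt(t)
    return PooledEstimate(
        estimate=qbar,
        within_var=wbar,
        between_var=b,
        total_var=float(t),
        ci_low=float(qbar - crit * se),
        ci_high=float(qbar + crit * se),
        df=float(df),
        m=m,
    )


_TRANSFORMS: dict[str, tuple[Callable, Callable, Callable]] = {
    # name -> (forward, inverse, d forward / d x) for delta-method variances
    "identity": (lambda x: x, lambda x: x, lambda x: np.ones_like(np.asarray(x, float))),
    "logit": (logit, expit, lambda p: 1.0 / (np.asarray(p, float) * (1 - np.asarray(p, float)))),
    "log": (np.log, np.exp, lambda x: 1.0 / np.asarray(x, float)),
}


def pool_transformed(
    estimates: Sequence[float],
    variances: Sequence[float],
    transform: str = "logit",
    df_com: Optional[float] = None,
) -> PooledEstimate:
    """Rubin pooling on a transformed scale with back-transformed interval.

    For bounded statistics (C-statistic, proportions) pooling on the logit
    scale keeps the combined estimate and interval inside (0, 1).  The
    returned within/between/total variances are on the transformed scale;
    estimate and CI are back-transformed.
    """
    if transform not in _TRANSFORMS:
        raise InputError(f"unknown transform {transform!r}")
    fwd, inv, grad = _TRANSFORMS[transform]
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    tq = fwd(q)
    tu = u * grad(q) ** 2
    pooled = pool_rubin(tq, tu, df_com=df_com)
    return PooledEstimate(
        estimate=float(inv(pooled.estimate)),
        within_var=pooled.within_var,
        between_var=pooled.between_var,
        total_var=pooled.total_var,
        ci_low=float(inv(pooled.ci_low)),
        ci_high=float(inv(pooled.ci_high)),
        df=pooled.df,
        m=pooled.m,
    )


@dataclass
class PerImputationResults:
    """Analysis outputs for every completed dataset plus one representative."""

    results: list
    representative_index: int

    @property
    def representative(self):
        return self.results[self.representative_index]


def per_imputation_outputs(
    imputed: ImputedCohortSet,
    analysis: Callable[[pd.DataFrame], object],
    seed: int = 0,
) -> PerImputationResults:
    """Run an analysis on each imputation; flag one seeded representative.

    Mirrors the reporting convention for plot-based analyses under multiple
    imputation: every imputed dataset is analysed and checked for
    similarity, and one randomly selected result is presented.
    """
    results = []
    failures = []
    for i, df in enumerate(imputed.imputations):
        try:
            results.append(analysis(df))
        except Exception as exc:
            failures.append((i, repr(exc)))
    if failures:
        raise AnalysisError(
            f"analysis failed on imputations {[i for i, _ in failures]}: {failures}",
            indices=[i for i, _ in failures],
        )
    rng = np.random.default_rng(derive_seed(seed, "representative"))
    rep = int(rng.integers(imputed.m))
    return PerImputationResults(results=results, representative_index=rep)
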