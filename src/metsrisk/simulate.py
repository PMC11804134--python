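"""Synthetic first-episode-psychosis cohorts for end-to-end testing.

Real validation cohorts of this kind are confidential clinical audit data,
so the pipeline is exercised on simulated cohorts whose *marginals* match
the published description of the study sample: n = 116, mean age 20.1
(SD 3.2), 73% male, 67% born in Australia, 65% non-smokers, 84% prescribed
a higher-metabolic-activity antipsychotic, follow-up 1–6 years with mean
2.6, and an incident metabolic-syndrome prevalence near 13%.

The generator draws baseline biomarkers through a Gaussian copula (the true
joint distribution is unknowable from published marginals; the default
correlations are deliberately modest and documented as fictional), computes
each participant's true log-odds from a configurable truth model — with an
optional calibration drift ``(delta, slope_factor)`` so miscalibration can
be planted and later recovered — targets the configured outcome prevalence
by solving for an intercept offset by bisection, draws the outcome as a
Bernoulli of the true risk, and then samples a follow-up biomarker panel
*conditional on the drawn outcome* by rejection against the IDF rule, so
the outcome classifier reproduces the drawn labels exactly.

A truth record (true risks, parameters, masks) accompanies every cohort so
downstream estimates can be verified without re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import (
    IDFCutoffs,
    MetabolicPanel,
    MetsStatus,
    ParticipantRecord,
    classify_mets_idf,
)
from .errors import FeasibilityError, InputError
from .missing_data import derive_seed
from .risk_model import RiskModel, load_model

__all__ = [
    "CohortSimConfig",
    "SimulationTruth",
    "generate_cohort",
    "inject_missingness",
    "default_true_model",
]

_BIOMARKERS = ("bmi", "waist", "hdl", "triglycerides", "sbp", "fasting_glucose")

#: fictional but physiologically plausible dependence among adiposity,
#: lipids, blood pressure and glucose (order: bmi, waist, hdl, tg, sbp, glu)
_DEFAULT_CORR = np.array(
    [
        [1.00, 0.80, -0.25, 0.30, 0.25, 0.15],
        [0.80, 1.00, -0.25, 0.30, 0.25, 0.15],
        [-0.25, -0.25, 1.00, -0.40, -0.10, -0.05],
        [0.30, 0.30, -0.40, 1.00, 0.15, 0.15],
        [0.25, 0.25, -0.10, 0.15, 1.00, 0.10],
        [0.15, 0.15, -0.05, 0.15, 0.10, 1.00],
    ]
)

_DEFAULT_MEANS = {
    "bmi": 23.5,
    "waist": 83.0,
    "hdl": 1.35,
    "triglycerides": 1.20,
    "sbp": 119.0,
    "fasting_glucose": 5.0,
}
_DEFAULT_SDS = {
    "bmi": 3.8,
    "waist": 11.0,
    "hdl": 0.28,
    "triglycerides": 0.55,
    "sbp": 11.0,
    "fasting_glucose": 0.45,
}

#: additive progression applied when drawing the follow-up panel;
#: (mean shift, shift SD) per biomarker, for non-cases and cases
_FOLLOWUP_DRIFT = {
    "bmi": ((0.8, 1.5), (3.5, 2.0)),
    "waist": ((2.0, 4.0), (12.0, 6.0)),
    "hdl": ((-0.02, 0.10), (-0.28, 0.15)),
    "triglycerides": ((0.05, 0.30), (0.80, 0.50)),
    "sbp": ((1.0, 6.0), (12.0, 8.0)),
    "fasting_glucose": ((0.05, 0.25), (0.60, 0.40)),
}

_VIOLATION_KINDS = ("age", "service", "baseline_window", "followup_window")


def default_true_model(variant: str = "full"):
    """The packaged synthetic reference model used as simulation truth."""
    from importlib.resources import files

    name = f"synthetic_reference_{variant}.yaml"
    return load_model(str(files("metsrisk.configs") / name))


@dataclass
class CohortSimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the published sample description; ``calibration_drift``
    ``(delta, slope_factor)`` transforms the truth-model linear predictor LP
    into true log-odds ``slope_factor·LP + delta`` (plus the prevalence-
    targeting offset), so (0, 1) means the truth *is* the model.
    """

    n: int = 116
    age_mean: float = 20.1
    age_sd: float = 3.2
    prop_male: float = 0.73
    prop_born_australia: float = 0.67
    prop_smoker: float = 0.35
    prop_higher_metabolic: float = 0.84
    prop_nonwhite_ethnicity: float = 0.35
    target_prevalence: Optional[float] = 0.13
    calibration_drift: tuple[float, float] = (0.0, 1.0)
    followup_mean_years: float = 2.6
    followup_range: tuple[float, float] = (1.0, 6.0)
    biomarker_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    biomarker_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    biomarker_corr: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    pulse_pressure_mean: float = 44.0
    pulse_pressure_sd: float = 7.0
    true_model: Optional[RiskModel] = None
    #: analysis-stage missingness (field -> rate), applied to the analysis
    #: table by the pipeline, not to the records themselves; the default
    #: mirrors the considerable missingness of blood results in routine
    #: clinical audit data
    missingness: Optional[dict] = field(
        default_factory=lambda: {"hdl": 0.2, "triglycerides": 0.2}
    )
    missingness_mechanism: str = "MCAR"
    plant_violations: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "prop_male",
            "prop_born_australia",
            "prop_smoker",
            "prop_higher_metabolic",
            "prop_nonwhite_ethnicity",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must be a probability, got {v}")
        if self.target_prevalence is not None and not 0 < self.target_prevalence < 1:
            raise InputError("target_prevalence must lie in (0, 1)")
        lo, hi = self.followup_range
        if not (1.0 <= lo < hi <= 6.0):
            raise InputError("followup_range must lie within [1, 6]")
        corr = np.asarray(self.biomarker_corr, dtype=float)
        if corr.shape != (len(_BIOMARKERS),) * 2 or not np.allclose(corr, corr.T):
            raise InputError("biomarker_corr must be a symmetric 6x6 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise InputError("biomarker_corr must be positive semi-definite")
        if not 0 <= self.plant_violations <= 1:
            raise InputError("plant_violations must be a fraction")
        if self.missingness:
            for col, rate in self.missingness.items():
                if not 0 <= rate < 1:
                    raise InputError(f"missingness rate for {col!r} must lie in [0, 1)")
        if self.missingness_mechanism not in ("MCAR", "MAR"):
            raise InputError("missingness_mechanism must be MCAR or MAR")


@dataclass
class SimulationTruth:
    """Everything needed to verify downstream estimates without re-simulation."""

    true_lp: np.ndarray  # truth-model linear predictor, before drift
    true_log_odds: np.ndarray  # after drift and prevalence offset
    true_risk: np.ndarray
    outcomes: np.ndarray
    intercept_offset: float
    calibration_drift: tuple[float, float]
    target_prevalence: Optional[float]
    seed: int
    planted_violations: dict[str, str] = field(default_factory=dict)  # id -> kind

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "true_lp": self.true_lp.tolist(),
                "true_log_odds": self.true_log_odds.tolist(),
                "true_risk": self.true_risk.tolist(),
                "outcomes": self.outcomes.tolist(),
                "intercept_offset": self.intercept_offset,
                "calibration_drift": list(self.calibration_drift),
                "target_prevalence": self.target_prevalence,
                "seed": self.seed,
                "planted_violations": self.planted_violations,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _truncated_normal(rng, mean, sd, low, high, size):
    """Truncated-normal draws whose *realised* mean equals ``mean``.

    Truncation shifts the mean of a plain truncated normal (cutting a
    16-year-old floor out of a distribution centred at 20 pulls the mean
    up), so the location parameter is solved such that the truncated
    distribution's expectation matches the requested mean.
    """

    def trunc_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    lo_bracket, hi_bracket = low - 6 * sd, high + 6 * sd
    target = min(max(mean, trunc_mean(lo_bracket) + 1e-9), trunc_mean(hi_bracket) - 1e-9)
    loc = brentq(lambda c: trunc_mean(c) - target, lo_bracket, hi_bracket)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _copula_biomarkers(rng, config: CohortSimConfig, size: int) -> dict[str, np.ndarray]:
    """Draw baseline biomarkers via a Gaussian copula.

    Triglycerides get a log-normal marginal (right-skewed, like real lipid
    panels); the rest are truncated normals.  Diastolic pressure is systolic
    minus an independent pulse pressure, which keeps dbp < sbp by
    construction.
    """
    chol = np.linalg.cholesky(
        np.asarray(config.biomarker_corr) + 1e-10 * np.eye(len(_BIOMARKERS))
    )
    z = rng.standard_normal((size, len(_BIOMARKERS))) @ chol.T
    u = stats.norm.cdf(z)
    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(_BIOMARKERS):
        mean, sd = config.biomarker_means[name], config.biomarker_sds[name]
        if name == "triglycerides":
            sigma2 = np.log(1 + (sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2
            out[name] = stats.lognorm.ppf(u[:, j], s=np.sqrt(sigma2), scale=np.exp(mu))
        else:
            low = max(mean - 4 * sd, 0.05 * mean)
            a, b = (low - mean) / sd, 4.0
            out[name] = stats.truncnorm.ppf(u[:, j], a, b, loc=mean, scale=sd)
    pulse = np.clip(
        rng.normal(config.pulse_pressure_mean, config.pulse_pressure_sd, size), 15, None
    )
    out["dbp"] = out["sbp"] - pulse
    out["dbp"] = np.clip(out["dbp"], 40, None)
    bad = out["dbp"] >= out["sbp"]
    out["dbp"][bad] = out["sbp"][bad] - 15.0
    return out


def _panel_from_row(values: dict[str, float]) -> MetabolicPanel:
    return MetabolicPanel(
        bmi=values["bmi"],
        waist=values["waist"],
        sbp=values["sbp"],
        dbp=values["dbp"],
        triglycerides=values["triglycerides"],
        hdl=values["hdl"],
        fasting_glucose=values["fasting_glucose"],
    )


def _draw_followup_panel(
    rng: np.random.Generator,
    baseline: dict[str, float],
    case: bool,
    sex: str,
    cutoffs: IDFCutoffs,
    max_tries: int = 1000,
) -> MetabolicPanel:
    """Rejection-sample a follow-up panel consistent with the drawn outcome.

    If early draws keep failing (extreme baselines), the progression means
    are nudged further in the conditioning direction every 50 attempts so
    the sampler terminates; the nudge only affects the far tails of the
    baseline distribution.
    """
    target = MetsStatus.POSITIVE if case else MetsStatus.NEGATIVE
    adverse_sign = {
        "bmi": 1.0,
        "waist": 1.0,
        "hdl": -1.0,
        "triglycerides": 1.0,
        "sbp": 1.0,
        "fasting_glucose": 1.0,
    }
    for attempt in range(max_tries):
        boost = 0.5 * (attempt // 50)
        values = {}
        for name, (none_shift, case_shift) in _FOLLOWUP_DRIFT.items():
            mu, sd = case_shift if case else none_shift
            nudge = adverse_sign[name] * boost * sd * (1.0 if case else -1.0)
            values[name] = baseline[name] + rng.normal(mu + nudge, sd)
        values["bmi"] = max(values["bmi"], 14.0)
        values["waist"] = max(values["waist"], 50.0)
        values["hdl"] = max(values["hdl"], 0.4)
        values["triglycerides"] = max(values["triglycerides"], 0.3)
        values["sbp"] = max(values["sbp"], 85.0)
        values["fasting_glucose"] = max(values["fasting_glucose"], 3.2)
        pulse = max(rng.normal(44.0, 7.0), 15.0)
        values["dbp"] = max(values["sbp"] - pulse, 40.0)
        if values["dbp"] >= values["sbp"]:
            values["dbp"] = values["sbp"] - 10.0
        panel = _panel_from_row(values)
        if classify_mets_idf(panel, sex, cutoffs=cutoffs) is target:
            return panel
    raise FeasibilityError(
        f"could not draw a follow-up panel classifying {target.value} for sex={sex} "
        f"within {max_tries} tries (baseline {baseline})"
    )


def _followup_years(rng, config: CohortSimConfig, size: int) -> np.ndarray:
    """Right-skewed follow-up time rescaled into the configured range."""
    lo, hi = config.followup_range
    target_mean = (config.followup_mean_years - lo) / (hi - lo)
    # Beta with fixed spread parameter, mean matched to the configured mean
    concentration = 5.0
    a = target_mean * concentration
    b = (1 - target_mean) * concentration
    return lo + (hi - lo) * rng.beta(a, b, size)


def generate_cohort(
    config: CohortSimConfig, cutoffs: IDFCutoffs = IDFCutoffs()
) -> tuple[list[ParticipantRecord], SimulationTruth]:
    """Simulate a cohort plus its truth record; deterministic given the seed.

    Baseline panels are redrawn until they classify IDF-negative, so every
    generated record (absent planted violations) passes the eligibility
    filter by construction.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    n = config.n
    model = config.true_model if config.true_model is not None else default_true_model()

    if n == 0:
        truth = SimulationTruth(
            true_lp=np.array([]),
            true_log_odds=np.array([]),
            true_risk=np.array([]),
            outcomes=np.array([], dtype=int),
            intercept_offset=0.0,
            calibration_drift=config.calibration_drift,
            target_prevalence=config.target_prevalence,
            seed=config.seed,
        )
        return [], truth

    age = _truncated_normal(rng, config.age_mean, config.age_sd, 16.0, 35.0, n)
    male = rng.random(n) < config.prop_male
    born_aus = rng.random(n) < config.prop_born_australia
    smoker = rng.random(n) < config.prop_smoker
    higher = rng.random(n) < config.prop_higher_metabolic
    nonwhite = rng.random(n) < config.prop_nonwhite_ethnicity

    bio = _copula_biomarkers(rng, config, n)
    # redraw baseline panels until IDF-negative (incidence cohort)
    for _ in range(200):
        bad = np.array(
            [
                classify_mets_idf(
                    _panel_from_row({k: bio[k][i] for k in (*_BIOMARKERS, "dbp")}),
                    "male" if male[i] else "female",
                    cutoffs=cutoffs,
                )
                is not MetsStatus.NEGATIVE
                for i in range(n)
            ],
            dtype=bool,
        )
        if not bad.any():
            break
        redraw = _copula_biomarkers(rng, config, int(bad.sum()))
        for k in (*_BIOMARKERS, "dbp"):
            bio[k][bad] = redraw[k]
    else:
        raise FeasibilityError("could not draw metabolic-syndrome-free baselines")

    records_wip = []
    for i in range(n):
        baseline_values = {k: float(bio[k][i]) for k in (*_BIOMARKERS, "dbp")}
        records_wip.append(
            {
                "id": f"P{i + 1:05d}",
                "age": float(age[i]),
                "sex": "male" if male[i] else "female",
                "born_in_australia": bool(born_aus[i]),
                "smoker": bool(smoker[i]),
                "antipsychotic_class": "higher_metabolic" if higher[i] else "lower_metabolic",
                "ethnicity": "non_white" if nonwhite[i] else "white",
                "baseline_values": baseline_values,
            }
        )

    # truth-model linear predictor on the drawn covariates
    lp = np.array(
        [
            model.linear_predictor(
                {
                    **r["baseline_values"],
                    "age": r["age"],
                    "sex": r["sex"],
                    "smoker": records_wip[i]["smoker"],
                    "antipsychotic_class": r["antipsychotic_class"],
                    "born_in_australia": r["born_in_australia"],
                    "ethnicity": r["ethnicity"],
                }
            )
            for i, r in enumerate(records_wip)
        ]
    )
    delta, slope_factor = config.calibration_drift
    drifted = slope_factor * lp + delta
    if config.target_prevalence is not None:
        offset = brentq(
            lambda c: expit(drifted + c).mean() - config.target_prevalence, -25, 25
        )
    else:
        offset = 0.0
    true_log_odds = drifted + offset
    true_risk = expit(true_log_odds)
    outcomes = (rng.random(n) < true_risk).astype(int)

    followup_years = _followup_years(rng, config, n)
    offsets = rng.integers(-100, 101, n)

    planted: dict[str, str] = {}
    if config.plant_violations > 0:
        n_bad = int(round(config.plant_violations * n))
        bad_idx = rng.choice(n, size=n_bad, replace=False)
        for j, i in enumerate(bad_idx):
            planted[records_wip[i]["id"]] = _VIOLATION_KINDS[j % len(_VIOLATION_KINDS)]

    records: list[ParticipantRecord] = []
    for i, r in enumerate(records_wip):
        violation = planted.get(r["id"])
        rec_age = r["age"]
        rec_offset = int(offsets[i])
        rec_fy = float(followup_years[i])
        in_service = True
        if violation == "age":
            rec_age = 36.0 + float(rng.random() * 5)
        elif violation == "service":
            in_service = False
        elif violation == "baseline_window":
            rec_offset = int(101 + rng.integers(0, 100))
        elif violation == "followup_window":
            rec_fy = 0.5
        followup_panel = _draw_followup_panel(
            rng, r["baseline_values"], bool(outcomes[i]), r["sex"], cutoffs
        )
        records.append(
            ParticipantRecord(
                id=r["id"],
                age=rec_age,
                sex=r["sex"],
                born_in_australia=r["born_in_australia"],
                smoker=r["smoker"],
                antipsychotic_class=r["antipsychotic_class"],
                baseline=_panel_from_row(r["baseline_values"]),
                baseline_offset_days=rec_offset,
                followup=followup_panel,
                followup_years=rec_fy,
                ethnicity=r["ethnicity"],
                treated_by_service=in_service,
            )
        )

    truth = SimulationTruth(
        true_lp=lp,
        true_log_odds=true_log_odds,
        true_risk=true_risk,
        outcomes=outcomes,
        intercept_offset=float(offset),
        calibration_drift=config.calibration_drift,
        target_prevalence=config.target_prevalence,
        seed=config.seed,
        planted_violations=planted,
    )
    return records, truth


def inject_missingness(
    frame: pd.DataFrame,
    rates: dict[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
    mar_driver: str = "age",
    mar_strength: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Punch missing-value holes into a cohort table; return (table, mask).

    MCAR removes each targeted cell independently with the given rate.  MAR
    makes the missingness probability a logistic function of a fully
    observed driver column (standardised), with the intercept solved so the
    expected overall rate matches the request.  The boolean mask marks the
    cells removed, for truth-aware tests.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise InputError(f"unknown mechanism {mechanism!r}")
    for col, rate in rates.items():
        if not 0 <= rate < 1:
            raise InputError(f"rate for {col!r} must lie in [0, 1), got {rate}")
        if col not in frame.columns:
            raise InputError(f"column {col!r} not in frame")
    rng = np.random.default_rng(derive_seed(seed, "missingness"))
    out = frame.copy()
    mask = pd.DataFrame(False, index=frame.index, columns=frame.columns)
    n = len(frame)
    if n == 0:
        return out, mask
    for col, rate in rates.items():
        if rate == 0:
            continue
        if mechanism == "MCAR":
            holes = rng.random(n) < rate
        else:
            driver = frame[mar_driver].to_numpy(dtype=float)
            if np.isnan(driver).any():
                raise InputError(f"MAR driver {mar_driver!r} must be fully observed")
            z = (driver - driver.mean()) / (driver.std() or 1.0)
            a = brentq(
                lambda a0: expit(a0 + mar_strength * z).mean() - rate, -30, 30
            )
            holes = rng.random(n) < expit(a + mar_strength * z)
        out.loc[holes, col] = np.nan
        mask.loc[holes, col] = True
    return out, mask
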