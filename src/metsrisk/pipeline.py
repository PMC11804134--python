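"""End-to-end study orchestration.

Runs the whole validation study in fixed order — eligibility filtering,
multiple imputation, application of the risk model(s), external validation,
recalibration / site-specific updating, re-validation, and decision-curve
analysis — from a single config, with every stochastic stage seeded from
one master seed, and produces a machine-readable :class:`StudyReport`
mirroring the before/after-updating results-table structure plus the tidy
data behind calibration and decision-curve plots.

Scalar performance estimates are computed in every imputed dataset and
pooled with Rubin's rules (the C-statistic on the logit scale); plot-shaped
outputs (decile tables, decision curves) come from one seeded
representative imputation, matching the usual reporting convention for
plot-based analyses under multiple imputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dca as _dca
from . import metrics as _metrics
from .cohort import (
    EligibilityReport,
    IDFCutoffs,
    ParticipantRecord,
    analysis_frame,
    apply_eligibility,
    read_cohort_csv,
)
from .errors import ConfigError, InputError
from .missing_data import (
    ImputedCohortSet,
    derive_seed,
    impute_chained,
    per_imputation_outputs,
    pool_rubin,
    pool_transformed,
)
from .risk_model import RiskModel, load_model, save_model
from .simulate import CohortSimConfig, generate_cohort
from .updating import recalibrate, refit_site_specific

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "StageResult", "run_study"]

STAGES = ("original", "recalibrated", "updated")


@dataclass
class StudyConfig:
    """Inputs and knobs of one study run.

    Either ``cohort_path`` (CSV in the cohort dialect) or ``sim`` (synthetic
    cohort spec; the default emulates the published sample description) must
    be supplied.  ``models`` maps variant labels to risk-model configs; the
    packaged synthetic reference models are used when omitted.
    """

    cohort_path: Optional[str] = None
    sim: Optional[CohortSimConfig] = None
    models: Optional[dict[str, RiskModel]] = None
    m: int = 10
    mice_iterations: int = 5
    bootstrap_replicates: int = 200
    dca_upper: float = 0.30
    dca_step: float = 0.01
    dca_key_threshold: float = 0.15
    stages: tuple[str, ...] = STAGES
    swap: Optional[dict[str, str]] = field(
        default_factory=lambda: {"ethnicity": "born_in_australia"}
    )
    ridge_penalty: Optional[float] = None  # None -> seeded cross-validation
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            cohort = raw["cohort"]
            if isinstance(cohort, str):
                kwargs["cohort_path"] = cohort
            elif "path" in cohort:
                kwargs["cohort_path"] = cohort["path"]
            elif "synthetic" in cohort:
                kwargs["sim"] = CohortSimConfig(**(cohort["synthetic"] or {}))
            else:
                raise ConfigError("cohort must give a path or a synthetic spec")
        if "models" in raw:
            kwargs["models"] = {k: load_model(v) for k, v in raw["models"].items()}
        mi = raw.get("mi", {})
        if "m" in mi:
            kwargs["m"] = int(mi["m"])
        if "iterations" in mi:
            kwargs["mice_iterations"] = int(mi["iterations"])
        if "bootstrap" in raw:
            kwargs["bootstrap_replicates"] = int(raw["bootstrap"].get("replicates", 200))
        if "dca" in raw:
            kwargs["dca_upper"] = float(raw["dca"].get("upper", 0.30))
            kwargs["dca_step"] = float(raw["dca"].get("step", 0.01))
        for key in ("stages", "seed", "outdir", "ridge_penalty", "swap"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "stages" else raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, RiskModel):
                return o.to_config()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StageResult:
    """Pooled validation of one model at one stage of the updating hierarchy."""

    stage: str
    pooled: dict  # metric name -> PooledEstimate
    decile_table: list[dict]
    decision_curve: _dca.DecisionCurve
    model_config: dict
    fitted_parameters: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "pooled": {
                k: dataclasses.asdict(v) for k, v in self.pooled.items()
            },
            "decile_table": self.decile_table,
            "decision_curve": self.decision_curve.to_frame().to_dict(orient="records"),
            "model_config": self.model_config,
            "fitted_parameters": self.fitted_parameters,
        }


@dataclass
class StudyReport:
    """Machine-readable record of a full study run."""

    eligibility: EligibilityReport
    n: int
    n_events: int
    prevalence: float
    results: dict[str, dict[str, StageResult]]  # variant -> stage -> result
    missingness_map: dict[str, float]
    m: int
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "eligibility": json.loads(self.eligibility.to_json()),
            "n": self.n,
            "n_events": self.n_events,
            "prevalence": self.prevalence,
            "results": {
                variant: {stage: sr.to_dict() for stage, sr in stages.items()}
                for variant, stages in self.results.items()
            },
            "missingness_map": self.missingness_map,
            "m": self.m,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def write_outputs(self, outdir: str | Path) -> Path:
        """Write report JSON, tidy plot data, and updated model configs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_json(outdir / "study_report.json")
        for variant, stages in self.results.items():
            for stage, sr in stages.items():
                pd.DataFrame(sr.decile_table).to_csv(
                    outdir / f"calibration_deciles_{variant}_{stage}.csv", index=False
                )
                sr.decision_curve.to_csv(
                    outdir / f"decision_curve_{variant}_{stage}.csv"
                )
                if stage != "original":
                    save_model(
                        load_model(sr.model_config),
                        outdir / f"model_{variant}_{stage}.yaml",
                    )
        return outdir


def _default_models() -> dict[str, RiskModel]:
    from .simulate import default_true_model

    return {"full": default_true_model("full"), "partial": default_true_model("partial")}


def _metric_estimates(model, table, y, replicates, seed):
    """Per-imputation metric estimates and variances for Rubin pooling."""
    pred = model.predict_frame(table)
    lp = pred["linear_predictor"].to_numpy()
    risks = pred["risk"].to_numpy()
    rng = np.random.default_rng(seed)
    out = {}
    for name, stat in (
        ("c_statistic", _metrics.c_statistic),
        ("r2_nagelkerke", _metrics.nagelkerke_r2),
        ("brier", _metrics.brier_score),
    ):
        est = stat(risks, y)
        se = _metrics.bootstrap_se(stat, risks, y, replicates=replicates, seed=rng)
        out[name] = (est, se**2)
    cal_int = _metrics.calibration_fit(lp, y, mode="intercept_only")
    cal_slope = _metrics.calibration_fit(lp, y, mode="intercept_slope")
    out["cal_intercept"] = (cal_int.intercept, cal_int.intercept_se**2)
    out["cal_slope"] = (cal_slope.slope, cal_slope.slope_se**2)
    return out, risks, lp


def _pooled_stage(
    stage: str,
    model: RiskModel,
    tables: Sequence[pd.DataFrame],
    y: np.ndarray,
    config: StudyConfig,
    seed: int,
    fitted_parameters: Optional[dict] = None,
) -> StageResult:
    per_imp = [
        _metric_estimates(
            model, t, y, config.bootstrap_replicates, derive_seed(seed, f"metrics_{i}")
        )
        for i, t in enumerate(tables)
    ]
    names = ("c_statistic", "r2_nagelkerke", "brier", "cal_intercept", "cal_slope")
    pooled = {}
    for name in names:
        ests = [p[0][name][0] for p in per_imp]
        vars_ = [p[0][name][1] for p in per_imp]
        if name == "c_statistic":
            pooled[name] = pool_transformed(ests, vars_, transform="logit")
        else:
            pooled[name] = pool_rubin(ests, vars_)
    rng = np.random.default_rng(derive_seed(seed, "representative"))
    rep = int(rng.integers(len(tables)))
    risks_rep = per_imp[rep][1]
    deciles = _metrics.calibration_deciles(risks_rep, y)
    curve = _dca.decision_curve(
        risks_rep,
        y,
        thresholds=_dca.default_threshold_grid(config.dca_upper, config.dca_step),
        bootstrap=_dca.BootstrapSpec(
            replicates=config.bootstrap_replicates, seed=derive_seed(seed, "dca")
        ),
    )
    return StageResult(
        stage=stage,
        pooled=pooled,
        decile_table=[dataclasses.asdict(b) for b in deciles],
        decision_curve=curve,
        model_config=model.to_config(),
        fitted_parameters=fitted_parameters,
    )


def _pooled_recalibration(model, tables, y) -> tuple[RiskModel, dict]:
    """Logistic calibration in every imputation; Rubin-pool (b0, b1)."""
    b0s, b0vars, b1s, b1vars = [], [], [], []
    for t in tables:
        res = recalibrate(model, t, y, method="logistic_calibration")
        (b0, b0se) = res.fitted_parameters["calibration_intercept"]
        (b1, b1se) = res.fitted_parameters["calibration_slope"]
        b0s.append(b0)
        b0vars.append(b0se**2)
        b1s.append(b1)
        b1vars.append(b1se**2)
    p0 = pool_rubin(b0s, b0vars)
    p1 = pool_rubin(b1s, b1vars)
    new_predictors = tuple(
        replace(p, coefficient=p1.estimate * p.coefficient) for p in model.predictors
    )
    updated = RiskModel(
        name=f"{model.name}_recalibrated",
        variant=model.variant,
        site="site_specific",
        intercept=p0.estimate + p1.estimate * model.intercept,
        predictors=new_predictors,
        provenance=f"pooled logistic calibration of {model.name}",
    )
    params = {
        "calibration_intercept": dataclasses.asdict(p0),
        "calibration_slope": dataclasses.asdict(p1),
    }
    return updated, params


def _pooled_refit(model, tables, y, config: StudyConfig, seed: int):
    """Ridge refit (with predictor swap) per imputation; pool coefficients."""
    swap = None
    if config.swap:
        applicable = {
            old: new
            for old, new in config.swap.items()
            if old in model.predictor_names and new in tables[0].columns
        }
        swap = applicable or None
    per_name: dict[str, tuple[list, list]] = {}
    template = None
    lambdas = []
    for i, t in enumerate(tables):
        res = refit_site_specific(
            model,
            t,
            y,
            swap=swap,
            penalty=config.ridge_penalty,
            seed=derive_seed(seed, f"refit_{i}"),
        )
        template = res.updated_model
        lambdas.append(res.convergence["ridge_lambda"])
        for name, (est, se) in res.fitted_parameters.items():
            per_name.setdefault(name, ([], []))[0].append(est)
            per_name[name][1].append(se**2)
    pooled_params = {
        name: pool_rubin(ests, vars_) for name, (ests, vars_) in per_name.items()
    }
    new_predictors = tuple(
        replace(p, coefficient=pooled_params[p.name].estimate)
        for p in template.predictors
    )
    updated = RiskModel(
        name=f"{model.name}_site_specific",
        variant=model.variant,
        site="site_specific",
        intercept=pooled_params["intercept"].estimate,
        predictors=new_predictors,
        provenance=f"pooled ridge refit of {model.name}"
        + (f" with swap {swap}" if swap else ""),
    )
    params = {k: dataclasses.asdict(v) for k, v in pooled_params.items()}
    params["ridge_lambda"] = {"per_imputation": lambdas}
    return updated, params


def run_study(config: StudyConfig | str | Path) -> StudyReport:
    """Execute the full study for one config; deterministic given its seed."""
    if isinstance(config, (str, Path)):
        config = StudyConfig.from_yaml(config)
    master = int(config.seed)

    # --- cohort -----------------------------------------------------------
    if config.cohort_path is not None:
        path = Path(config.cohort_path)
        if not path.exists():
            raise ConfigError(f"cohort file not found: {path}")
        records = read_cohort_csv(path)
        truth = None
        sim = None
    else:
        sim = config.sim if config.sim is not None else CohortSimConfig()
        sim = replace(sim, seed=derive_seed(master, "simulate"))
        records, truth = generate_cohort(sim)
    logger.info("cohort loaded: n=%d", len(records))

    # --- eligibility ------------------------------------------------------
    eligibility = apply_eligibility(records)
    included_ids = set(eligibility.included)
    included = [r for r in records if r.id in included_ids]
    logger.info(
        "eligibility: %d included, %d excluded", len(included), eligibility.n_excluded
    )
    if not included:
        raise InputError("no eligible participants")

    frame = analysis_frame(included).drop(columns=["id"])
    if sim is not None and sim.missingness:
        from .simulate import inject_missingness

        rates = {c: r for c, r in sim.missingness.items() if c in frame.columns}
        frame, _ = inject_missingness(
            frame,
            rates,
            mechanism=sim.missingness_mechanism,
            seed=derive_seed(master, "missingness"),
        )
    y = frame["outcome"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise InputError("indeterminate outcomes survived eligibility filtering")
    predictors_frame = frame.drop(columns=["outcome"])
    n, n_events = len(y), int(y.sum())
    logger.info("analysis sample: n=%d, events=%d", n, n_events)

    # --- multiple imputation ---------------------------------------------
    work = frame.copy()
    missing_any = predictors_frame.isna().any().any()
    if missing_any:
        imputed = impute_chained(
            work,
            m=config.m,
            iterations=config.mice_iterations,
            seed=derive_seed(master, "mice"),
        )
        tables = [t.drop(columns=["outcome"]) for t in imputed.imputations]
        missingness_map = imputed.missingness_map
        m_eff = config.m
        logger.info("imputation: m=%d, iterations=%d", config.m, config.mice_iterations)
    else:
        tables = [predictors_frame]
        missingness_map = {c: 0.0 for c in work.columns}
        m_eff = 1
        logger.info("no missing values: single complete-data analysis")

    # --- models and stages -------------------------------------------------
    models = config.models if config.models is not None else _default_models()
    results: dict[str, dict[str, StageResult]] = {}
    for variant, model in models.items():
        stage_results: dict[str, StageResult] = {}
        if "original" in config.stages:
            stage_results["original"] = _pooled_stage(
                "original",
                model,
                tables,
                y,
                config,
                derive_seed(master, f"{variant}_original"),
            )
            logger.info(
                "%s original: C=%.3f",
                variant,
                stage_results["original"].pooled["c_statistic"].estimate,
            )
        if "recalibrated" in config.stages:
            recal_model, recal_params = _pooled_recalibration(model, tables, y)
            stage_results["recalibrated"] = _pooled_stage(
                "recalibrated",
                recal_model,
                tables,
                y,
                config,
                derive_seed(master, f"{variant}_recalibrated"),
                fitted_parameters=recal_params,
            )
            logger.info(
                "%s recalibrated: slope b1=%.3f",
                variant,
                recal_params["calibration_slope"]["estimate"],
            )
        if "updated" in config.stages:
            refit_model, refit_params = _pooled_refit(
                model, tables, y, config, derive_seed(master, f"{variant}_refit")
            )
            stage_results["updated"] = _pooled_stage(
                "updated",
                refit_model,
                tables,
                y,
                config,
                derive_seed(master, f"{variant}_updated"),
                fitted_parameters=refit_params,
            )
        results[variant] = stage_results

    metadata = {
        "seed": master,
        "config_hash": config.config_hash(),
        "m": m_eff,
        "mice_iterations": config.mice_iterations,
        "bootstrap_replicates": config.bootstrap_replicates,
        "stages": list(config.stages),
        "synthetic": config.cohort_path is None,
    }
    report = StudyReport(
        eligibility=eligibility,
        n=n,
        n_events=n_events,
        prevalence=n_events / n,
        results=results,
        missingness_map=missingness_map,
        m=m_eff,
        metadata=metadata,
    )
    if config.outdir is not None:
        report.write_outputs(config.outdir)
    return report
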