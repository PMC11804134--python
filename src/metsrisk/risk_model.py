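"""Penalised-logistic risk equations of the PsyMetRiC family.

A :class:`RiskModel` is a frozen description of a published (or refitted)
logistic risk score: an intercept plus per-predictor log-odds coefficients
with explicit encodings from raw values to design values.  Coefficients are
data, not code — they are loaded from a YAML/JSON config whose structure
mirrors the published coefficient tables.  The repository ships a template
with placeholder values (``configs/psymetric_template.yaml``) to be filled
from the original open-access publication, plus a clearly-labelled synthetic
reference model used by the simulator and the test-suite.

The linear predictor is ``intercept + sum(coef * encoded value)`` and the
predicted probability its inverse logit.  Any LASSO/ridge shrinkage applied
at development time is assumed to be folded into the published coefficients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import (
    ConfigError,
    ConsistencyError,
    InputError,
    MissingPredictorError,
    UnknownDrugError,
)

__all__ = [
    "PredictorSpec",
    "RiskModel",
    "RiskPrediction",
    "load_model",
    "save_model",
    "categorize_antipsychotic",
    "load_drug_lookup",
    "predict",
]

_KINDS = ("continuous", "binary", "categorical")
#: predictor names that identify the biochemical block absent from the
#: partial-model variant
_LIPID_NAMES = ("hdl", "triglycerides")

_TRANSFORMS = {
    "identity": lambda x: x,
    "log": math.log,
    "log10": math.log10,
}


def _normalise_key(value: Any) -> Any:
    """Map raw categorical values onto comparable keys (case/space folded)."""
    if isinstance(value, str):
        return value.strip().lower()
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return value


@dataclass(frozen=True)
class PredictorSpec:
    """One term of a logistic risk equation.

    Parameters
    ----------
    name
        Identifier matching a field of the participant record
        (e.g. ``"bmi"``, ``"sex"``, ``"antipsychotic_class"``).
    kind
        ``continuous`` | ``binary`` | ``categorical``.
    coefficient
        Log-odds per encoded unit.
    encoding
        For binary/categorical kinds: a mapping from raw level to design
        value covering every declared level exactly once.  For continuous
        kinds: optionally ``{"transform": "log"}`` etc.; default identity.
    """

    name: str
    kind: str
    coefficient: float
    encoding: Mapping[Any, float] | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(
                f"predictor {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {_KINDS}"
            )
        if not np.isfinite(self.coefficient):
            raise ConfigError(f"predictor {self.name!r}: non-finite coefficient")
        if self.kind == "categorical" and not self.encoding:
            raise ConfigError(
                f"categorical predictor {self.name!r} requires an encoding"
            )
        if self.encoding and self.kind != "continuous":
            norm = [_normalise_key(k) for k in self.encoding]
            if len(set(norm)) != len(norm):
                raise ConfigError(
                    f"predictor {self.name!r}: encoding levels collide after "
                    "case/whitespace normalisation"
                )

    def encode(self, raw: Any) -> float:
        """Map a raw field value to its design value."""
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            raise MissingPredictorError(self.name)
        if self.kind == "continuous":
            value = float(raw)
            if not math.isfinite(value):
                raise InputError(f"predictor {self.name!r}: non-finite value {raw!r}")
            transform = "identity"
            if self.encoding:
                transform = self.encoding.get("transform", "identity")
            try:
                return float(_TRANSFORMS[transform](value))
            except KeyError:
                raise ConfigError(
                    f"predictor {self.name!r}: unknown transform {transform!r}"
                ) from None
        # binary / categorical
        if self.encoding:
            key = _normalise_key(raw)
            table = {_normalise_key(k): v for k, v in self.encoding.items()}
            if key in table:
                return float(table[key])
            # already-encoded design values pass through (0/1 columns built
            # upstream, e.g. by the imputation stage)
            if isinstance(raw, (int, float, np.integer, np.floating)) and float(
                raw
            ) in {float(v) for v in self.encoding.values()}:
                return float(raw)
            raise InputError(
                f"predictor {self.name!r}: value {raw!r} not in declared levels "
                f"{sorted(map(str, self.encoding))}"
            )
        if self.kind == "binary":
            return 1.0 if bool(raw) else 0.0
        raise ConfigError(f"categorical predictor {self.name!r} has no encoding")


@dataclass(frozen=True)
class RiskModel:
    """A named logistic risk equation (full or partial variant)."""

    name: str
    variant: str  # {"full", "partial"}
    site: str  # {"UK", "site_specific"}
    intercept: float
    predictors: tuple[PredictorSpec, ...]
    provenance: str = ""

    def __post_init__(self):
        if self.variant not in ("full", "partial"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if not np.isfinite(self.intercept):
            raise ConfigError("intercept must be finite")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ConsistencyError(f"duplicate predictor names in {self.name!r}")
        if self.variant == "partial":
            lipids = [n for n in names if n.lower() in _LIPID_NAMES]
            if lipids:
                raise ConsistencyError(
                    f"partial-model variant must not contain biochemical "
                    f"predictors, found {lipids}"
                )

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.predictors)

    def linear_predictor(self, record: Mapping[str, Any]) -> float:
        """Intercept plus coefficient-weighted sum of encoded values."""
        getter = getattr(record, "predictor_values", None)
        values = getter() if callable(getter) else record
        lp = self.intercept
        for spec in self.predictors:
            try:
                raw = values[spec.name]
            except KeyError:
                raise MissingPredictorError(spec.name) from None
            lp += spec.coefficient * spec.encode(raw)
        return lp

    def predict(self, record: Mapping[str, Any]) -> "RiskPrediction":
        return predict(self, record)

    def linear_predictor_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Vectorised linear predictor over a cohort table.

        Columns must be named after the predictors; values may be raw levels
        or already-encoded design values.
        """
        lp = np.full(len(frame), float(self.intercept))
        for spec in self.predictors:
            if spec.name not in frame.columns:
                raise MissingPredictorError(spec.name)
            col = frame[spec.name]
            encoded = np.array([spec.encode(v) for v in col], dtype=float)
            lp += spec.coefficient * encoded
        return lp

    def predict_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        lp = self.linear_predictor_frame(frame)
        return pd.DataFrame(
            {"linear_predictor": lp, "risk": expit(lp)}, index=frame.index
        )

    def to_config(self) -> dict:
        """Serialise to the same structure :func:`load_model` reads."""
        return {
            "name": self.name,
            "variant": self.variant,
            "site": self.site,
            "intercept": float(self.intercept),
            "provenance": self.provenance,
            "predictors": [
                {
                    "name": p.name,
                    "kind": p.kind,
                    "coefficient": float(p.coefficient),
                    **(
                        {"encoding": {str(k): v for k, v in p.encoding.items()}}
                        if p.encoding
                        else {}
                    ),
                }
                for p in self.predictors
            ],
        }


@dataclass(frozen=True)
class RiskPrediction:
    """A single model output: log-odds and probability."""

    linear_predictor: float
    risk: float

    def __post_init__(self):
        if not np.isclose(self.risk, expit(self.linear_predictor), atol=1e-10):
            raise InputError("risk must equal inverse-logit(linear_predictor)")


def predict(model: RiskModel, record: Mapping[str, Any]) -> RiskPrediction:
    """Apply ``model`` to one participant record.

    Raises :class:`MissingPredictorError` when the record lacks a declared
    predictor — the caller decides whether and how to impute.
    """
    lp = model.linear_predictor(record)
    return RiskPrediction(linear_predictor=lp, risk=float(expit(lp)))


# ---------------------------------------------------------------------------
# config I/O


def _coerce_encoding(raw: Mapping[Any, Any] | None) -> dict | None:
    if raw is None:
        return None
    out = {}
    for k, v in raw.items():
        # YAML may give bools/ints as keys; JSON only strings
        if isinstance(k, str) and k.lower() in ("true", "false"):
            k = k.lower() == "true"
        out[k] = v
    return out


def load_model(source: str | Path | Mapping[str, Any]) -> RiskModel:
    """Load and validate a risk-model config (YAML/JSON path or mapping).

    The config must declare ``name``, ``variant``, ``intercept`` and a
    ``predictors`` list of ``{name, kind, coefficient, encoding?}`` entries.
    Inconsistent configs (partial variant with lipid predictors, unknown
    predictor kinds, missing intercept) are rejected.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        cfg = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
    else:
        cfg = dict(source)
    if not isinstance(cfg, Mapping):
        raise ConfigError("model config must be a mapping")
    for key in ("name", "variant", "intercept", "predictors"):
        if key not in cfg:
            raise ConfigError(f"model config missing required key {key!r}")
    if cfg["intercept"] is None or not np.isfinite(float(cfg["intercept"])):
        raise ConfigError("model config intercept must be a finite number")
    predictors = []
    for entry in cfg["predictors"]:
        if "coefficient" not in entry or entry["coefficient"] is None:
            raise ConfigError(
                f"predictor {entry.get('name', '?')!r} missing coefficient "
                "(placeholder template not filled in?)"
            )
        predictors.append(
            PredictorSpec(
                name=entry["name"],
                kind=entry.get("kind", "continuous"),
                coefficient=float(entry["coefficient"]),
                encoding=_coerce_encoding(entry.get("encoding")),
            )
        )
    return RiskModel(
        name=str(cfg["name"]),
        variant=str(cfg["variant"]),
        site=str(cfg.get("site", "UK")),
        intercept=float(cfg["intercept"]),
        predictors=tuple(predictors),
        provenance=str(cfg.get("provenance", "")),
    )


def save_model(model: RiskModel, path: str | Path) -> Path:
    """Write a model config; format chosen by extension (.yaml/.json)."""
    path = Path(path)
    cfg = model.to_config()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# antipsychotic metabolic-activity classification

HIGHER_METABOLIC = "higher_metabolic"
LOWER_METABOLIC = "lower_metabolic"


def load_drug_lookup(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV (drug_name, class) into a normalised lookup."""
    table = pd.read_csv(path)
    cols = [c.strip().lower() for c in table.columns]
    if "drug_name" not in cols or "class" not in cols:
        raise ConfigError("drug lookup CSV must have columns drug_name, class")
    table.columns = cols
    lookup = {}
    for _, row in table.iterrows():
        lookup[str(row["drug_name"]).strip().lower()] = str(row["class"]).strip()
    bad = {v for v in lookup.values()} - {HIGHER_METABOLIC, LOWER_METABOLIC}
    if bad:
        raise ConfigError(f"drug lookup contains unknown classes: {sorted(bad)}")
    return lookup


def categorize_antipsychotic(drug_name: str, lookup: Mapping[str, str]) -> str:
    """Classify an antipsychotic as higher- or lower-metabolic-activity.

    Lookup is case-insensitive and whitespace-trimmed.  A drug absent from
    the lookup raises :class:`UnknownDrugError`; unknown drugs are never
    defaulted to a class, because silent misclassification corrupts the
    exposure — the eligibility stage decides what to do with them.
    """
    key = str(drug_name).strip().lower()
    table = {str(k).strip().lower(): v for k, v in lookup.items()}
    if key not in table:
        raise UnknownDrugError(drug_name)
    return table[key]
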