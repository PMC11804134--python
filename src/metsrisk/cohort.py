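"""Participant schema, IDF metabolic-syndrome rule, and eligibility filter.

The outcome is IDF-consensus metabolic syndrome: central obesity (sex-specific
waist cut-off, or BMI > 30 when waist is unavailable) together with at least
two of raised triglycerides, reduced HDL-cholesterol, raised blood pressure
and raised fasting glucose.  The classifier is three-valued: when missing
components leave both verdicts possible under some completion of the data it
returns ``indeterminate`` rather than guessing.

Eligibility reproduces a first-episode-psychosis validation cohort's
inclusion rules: age 16–35 at diagnosis, treated by the service, baseline
measures within ±100 days of diagnosis, free of metabolic syndrome at
baseline, follow-up measures 1–6 years later, and complete enough data to
classify the outcome.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "MetabolicPanel",
    "ParticipantRecord",
    "MetsStatus",
    "IDFCutoffs",
    "EligibilityReport",
    "classify_mets_idf",
    "apply_eligibility",
    "analysis_frame",
    "records_to_frame",
    "frame_to_records",
    "read_cohort_csv",
    "write_cohort_csv",
    "ELIGIBILITY_CRITERIA",
]


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class MetabolicPanel:
    """One anthropometric/biochemical assessment; any field may be missing.

    Units: BMI kg/m², waist cm, blood pressure mmHg, lipids and glucose
    mmol/L.
    """

    bmi: Optional[float] = None
    waist: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    triglycerides: Optional[float] = None
    hdl: Optional[float] = None
    fasting_glucose: Optional[float] = None

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is not None and not _is_missing(v) and float(v) <= 0:
                raise InputError(f"panel field {f.name} must be positive, got {v}")
        if (
            not _is_missing(self.sbp)
            and not _is_missing(self.dbp)
            and float(self.dbp) >= float(self.sbp)
        ):
            raise InputError(
                f"diastolic ({self.dbp}) must be below systolic ({self.sbp})"
            )

    def get(self, name: str) -> Optional[float]:
        v = getattr(self, name)
        return None if _is_missing(v) else float(v)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: baseline covariates, follow-up measures, follow-up time."""

    id: str
    age: float
    sex: str  # {"male", "female"}
    born_in_australia: bool
    smoker: bool
    antipsychotic_class: str  # {"higher_metabolic", "lower_metabolic"}
    baseline: MetabolicPanel
    baseline_offset_days: int
    followup: Optional[MetabolicPanel] = None
    followup_years: Optional[float] = None
    ethnicity: Optional[str] = None
    treated_by_service: bool = True
    treatment_flags: frozenset = frozenset()

    def __post_init__(self):
        if self.age <= 0:
            raise InputError(f"{self.id}: age must be positive")
        if self.sex not in ("male", "female"):
            raise InputError(f"{self.id}: sex must be male/female, got {self.sex!r}")
        if self.followup is not None and (
            self.followup_years is None or self.followup_years <= 0
        ):
            raise InputError(
                f"{self.id}: followup_years must be positive when follow-up present"
            )

    def predictor_values(self) -> dict[str, Any]:
        """Raw values keyed by the predictor names risk models use."""
        values = {
            "age": self.age,
            "sex": self.sex,
            "smoker": self.smoker,
            "antipsychotic_class": self.antipsychotic_class,
            "born_in_australia": self.born_in_australia,
            "ethnicity": self.ethnicity,
        }
        for name in ("bmi", "hdl", "triglycerides", "waist", "sbp", "dbp",
                     "fasting_glucose"):
            values[name] = self.baseline.get(name)
        return values


class MetsStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class IDFCutoffs:
    """IDF component cut-offs; defaults are the Europid consensus values.

    Ethnicity-specific waist thresholds can be supplied by constructing a
    custom instance.
    """

    waist_male: float = 94.0
    waist_female: float = 80.0
    bmi_obesity: float = 30.0
    triglycerides: float = 1.7
    hdl_male: float = 1.03
    hdl_female: float = 1.29
    sbp: float = 130.0
    dbp: float = 85.0
    glucose: float = 5.6


#: names accepted in ``treated_flags`` and the component they satisfy
TREATED_COMPONENTS = ("triglycerides", "hdl", "blood_pressure", "glucose")


def _tri(value: Optional[float], satisfied_when) -> Optional[bool]:
    """Three-valued component check: True/False/None(=unknown)."""
    if value is None:
        return None
    return bool(satisfied_when(value))


def classify_mets_idf(
    panel: MetabolicPanel,
    sex: str,
    treated_flags: Optional[Iterable[str]] = None,
    cutoffs: IDFCutoffs = IDFCutoffs(),
) -> MetsStatus:
    """Apply the IDF metabolic-syndrome rule to one assessment.

    Positive requires central obesity — waist at or above the sex-specific
    threshold, or BMI above 30 when waist is missing (both present: waist
    governs) — plus at least two of: raised triglycerides (≥ 1.7 mmol/L),
    reduced HDL (< 1.03 male / 1.29 female mmol/L), raised blood pressure
    (SBP ≥ 130 or DBP ≥ 85 mmHg), raised fasting glucose (≥ 5.6 mmol/L).
    Drug treatment for a component (named in ``treated_flags``) counts as
    that component being present.

    Returns ``indeterminate`` exactly when the missing fields leave both a
    positive and a negative completion possible.
    """
    if sex not in ("male", "female"):
        raise InputError(f"sex must be male/female, got {sex!r}")
    flags = {str(f).strip().lower() for f in (treated_flags or ())}
    unknown_flags = flags - set(TREATED_COMPONENTS)
    if unknown_flags:
        raise InputError(f"unknown treated_flags: {sorted(unknown_flags)}")

    # central obesity: waist governs when present; BMI>30 proxies otherwise
    waist = panel.get("waist")
    waist_cut = cutoffs.waist_male if sex == "male" else cutoffs.waist_female
    if waist is not None:
        obesity: Optional[bool] = waist >= waist_cut
    else:
        bmi = panel.get("bmi")
        obesity = None if bmi is None else bmi > cutoffs.bmi_obesity

    hdl_cut = cutoffs.hdl_male if sex == "male" else cutoffs.hdl_female
    components: list[Optional[bool]] = []
    if "triglycerides" in flags:
        components.append(True)
    else:
        components.append(_tri(panel.get("triglycerides"), lambda v: v >= cutoffs.triglycerides))
    if "hdl" in flags:
        components.append(True)
    else:
        components.append(_tri(panel.get("hdl"), lambda v: v < hdl_cut))
    if "blood_pressure" in flags:
        components.append(True)
    else:
        sbp, dbp = panel.get("sbp"), panel.get("dbp")
        if sbp is not None and sbp >= cutoffs.sbp:
            components.append(True)
        elif dbp is not None and dbp >= cutoffs.dbp:
            components.append(True)
        elif sbp is not None and dbp is not None:
            components.append(False)
        else:
            components.append(None)  # the unmeasured pressure could qualify
    if "glucose" in flags:
        components.append(True)
    else:
        components.append(_tri(panel.get("fasting_glucose"), lambda v: v >= cutoffs.glucose))

    n_min = sum(1 for c in components if c is True)
    n_max = sum(1 for c in components if c is not False)

    possibly_positive = (obesity is not False) and n_max >= 2
    possibly_negative = (obesity is not True) or n_min < 2
    if possibly_positive and possibly_negative:
        return MetsStatus.INDETERMINATE
    return MetsStatus.POSITIVE if possibly_positive else MetsStatus.NEGATIVE


# ---------------------------------------------------------------------------
# eligibility

ELIGIBILITY_CRITERIA = (
    "age_16_35",
    "treated_by_service",
    "baseline_within_100_days",
    "no_baseline_mets",
    "followup_1_to_6_years",
    "complete_data",
)


@dataclass
class EligibilityReport:
    """CONSORT-style partition of a candidate cohort."""

    included: list[str]
    excluded: list[tuple[str, str]]  # (id, first failed criterion)
    counts: dict[str, int]

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "included": self.included,
                "excluded": [list(e) for e in self.excluded],
                "counts": self.counts,
                "n_included": self.n_included,
                "n_excluded": self.n_excluded,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _first_failed_criterion(
    record: ParticipantRecord, cutoffs: IDFCutoffs
) -> Optional[str]:
    if not (16 <= record.age <= 35):
        return "age_16_35"
    if not record.treated_by_service:
        return "treated_by_service"
    if abs(int(record.baseline_offset_days)) > 100:  # inclusive at ±100
        return "baseline_within_100_days"
    baseline_status = classify_mets_idf(
        record.baseline, record.sex, record.treatment_flags, cutoffs
    )
    # indeterminate baselines are excluded conservatively: a possibly
    # prevalent case must not enter an incidence cohort
    if baseline_status is not MetsStatus.NEGATIVE:
        return "no_baseline_mets"
    if record.followup_years is None or not (1.0 <= record.followup_years <= 6.0):
        return "followup_1_to_6_years"
    if record.followup is None:
        return "complete_data"
    followup_status = classify_mets_idf(
        record.followup, record.sex, record.treatment_flags, cutoffs
    )
    if followup_status is MetsStatus.INDETERMINATE:
        return "complete_data"
    return None


def apply_eligibility(
    records: Sequence[ParticipantRecord], cutoffs: IDFCutoffs = IDFCutoffs()
) -> EligibilityReport:
    """Partition records into included/excluded with first-failure reporting.

    Criteria are checked in a fixed order (age, service, baseline window,
    baseline metabolic syndrome, follow-up window, data completeness) so the
    per-criterion counts are deterministic.  Idempotent: filtering an
    already-included set changes nothing.
    """
    included: list[str] = []
    excluded: list[tuple[str, str]] = []
    counts = {c: 0 for c in ELIGIBILITY_CRITERIA}
    for record in records:
        failed = _first_failed_criterion(record, cutoffs)
        if failed is None:
            included.append(record.id)
        else:
            excluded.append((record.id, failed))
            counts[failed] += 1
    return EligibilityReport(included=included, excluded=excluded, counts=counts)


# ---------------------------------------------------------------------------
# flat-file I/O (one row per participant; panel fields prefixed)

_PANEL_FIELDS = ("bmi", "waist", "sbp", "dbp", "triglycerides", "hdl", "fasting_glucose")


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, Any] = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "born_in_australia": r.born_in_australia,
            "smoker": r.smoker,
            "antipsychotic_class": r.antipsychotic_class,
            "ethnicity": r.ethnicity,
            "baseline_offset_days": r.baseline_offset_days,
            "followup_years": r.followup_years,
            "treated_by_service": r.treated_by_service,
        }
        for f in _PANEL_FIELDS:
            row[f"baseline_{f}"] = r.baseline.get(f)
            row[f"followup_{f}"] = r.followup.get(f) if r.followup else None
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for _, row in frame.iterrows():
        def panel(prefix: str) -> MetabolicPanel:
            kwargs = {}
            for f in _PANEL_FIELDS:
                v = row.get(f"{prefix}_{f}")
                kwargs[f] = None if pd.isna(v) else float(v)
            return MetabolicPanel(**kwargs)

        followup = panel("followup")
        if all(followup.get(f) is None for f in _PANEL_FIELDS):
            followup = None
        fy = row.get("followup_years")
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                born_in_australia=bool(row["born_in_australia"]),
                smoker=bool(row["smoker"]),
                antipsychotic_class=str(row["antipsychotic_class"]),
                baseline=panel("baseline"),
                baseline_offset_days=int(row["baseline_offset_days"]),
                followup=followup,
                followup_years=None if pd.isna(fy) else float(fy),
                ethnicity=None
                if pd.isna(row.get("ethnicity"))
                else str(row.get("ethnicity")),
                treated_by_service=bool(row.get("treated_by_service", True)),
            )
        )
    return records


def analysis_frame(
    records: Sequence[ParticipantRecord],
    cutoffs: IDFCutoffs = IDFCutoffs(),
    include_outcome: bool = True,
) -> pd.DataFrame:
    """Numeric analysis table: encoded predictors plus the follow-up outcome.

    Binary fields are encoded 0/1 (male=1, smoker=1, higher-metabolic
    antipsychotic=1, born in Australia=1, non-white ethnicity=1 when known);
    biochemical fields come from the baseline panel and may be NaN (to be
    multiply imputed).  The outcome column is the IDF classification of the
    follow-up panel (positive=1); indeterminate follow-ups yield NaN and
    should have been removed by eligibility filtering.
    """
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age": r.age,
            "sex": 1.0 if r.sex == "male" else 0.0,
            "smoker": 1.0 if r.smoker else 0.0,
            "antipsychotic_class": 1.0 if r.antipsychotic_class == "higher_metabolic" else 0.0,
            "born_in_australia": 1.0 if r.born_in_australia else 0.0,
            "bmi": r.baseline.get("bmi"),
            "hdl": r.baseline.get("hdl"),
            "triglycerides": r.baseline.get("triglycerides"),
        }
        if r.ethnicity is not None:
            row["ethnicity"] = 0.0 if r.ethnicity.strip().lower() == "white" else 1.0
        else:
            row["ethnicity"] = 0.0
        if include_outcome:
            if r.followup is None:
                row["outcome"] = np.nan
            else:
                status = classify_mets_idf(r.followup, r.sex, r.treatment_flags, cutoffs)
                row["outcome"] = (
                    np.nan
                    if status is MetsStatus.INDETERMINATE
                    else float(status is MetsStatus.POSITIVE)
                )
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame[["age", "bmi", "hdl", "triglycerides"]] = frame[
        ["age", "bmi", "hdl", "triglycerides"]
    ].astype(float)
    return frame


def read_cohort_csv(path: str | Path) -> list[ParticipantRecord]:
    return frame_to_records(pd.read_csv(path))


def write_cohort_csv(records: Sequence[ParticipantRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path
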