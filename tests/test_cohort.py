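"""IDF metabolic-syndrome rule (incl. brute-force oracle) and eligibility."""

import itertools

import numpy as np
import pytest

from metsrisk.cohort import (
    IDFCutoffs,
    MetabolicPanel,
    MetsStatus,
    apply_eligibility,
    classify_mets_idf,
    frame_to_records,
    records_to_frame,
)
from metsrisk.errors import InputError

CUT = IDFCutoffs()


def panel(**kwargs):
    defaults = dict(
        bmi=23.0,
        waist=85.0,
        sbp=118.0,
        dbp=74.0,
        triglycerides=1.2,
        hdl=1.4,
        fasting_glucose=4.9,
    )
    defaults.update(kwargs)
    return MetabolicPanel(**defaults)


class TestClassifyMetsIDF:
    def test_all_normal_is_negative(self):
        assert classify_mets_idf(panel(), "male") is MetsStatus.NEGATIVE

    def test_obesity_plus_two_components_is_positive(self):
        p = panel(waist=95.0, triglycerides=1.8, hdl=1.00)
        assert classify_mets_idf(p, "male") is MetsStatus.POSITIVE

    def test_obesity_plus_single_component_is_negative(self):
        p = panel(waist=95.0, triglycerides=1.8)
        assert classify_mets_idf(p, "male") is MetsStatus.NEGATIVE

    def test_bmi_substitutes_only_when_waist_missing(self):
        p = MetabolicPanel(
            bmi=31.0,
            waist=None,
            sbp=135.0,
            dbp=74.0,
            triglycerides=1.2,
            hdl=1.4,
            fasting_glucose=5.7,
        )
        assert classify_mets_idf(p, "male") is MetsStatus.POSITIVE
        # waist present and below threshold: waist governs despite BMI > 30
        assert (
            classify_mets_idf(panel(bmi=31.0, waist=88.0, sbp=135.0, fasting_glucose=5.7), "male")
            is MetsStatus.NEGATIVE
        )

    def test_sex_specific_cutoffs(self):
        p = panel(waist=82.0, triglycerides=1.8, hdl=1.2)
        # female: waist 82 >= 80 obese, HDL 1.2 < 1.29 reduced -> positive
        assert classify_mets_idf(p, "female") is MetsStatus.POSITIVE
        # male: waist 82 < 94 -> not obese
        assert classify_mets_idf(p, "male") is MetsStatus.NEGATIVE

    def test_treated_flags_count_as_component_positive(self):
        p = panel(waist=95.0, triglycerides=1.8)
        assert (
            classify_mets_idf(p, "male", treated_flags={"blood_pressure"})
            is MetsStatus.POSITIVE
        )

    def test_indeterminate_when_missingness_leaves_both_verdicts(self):
        # obese; one component positive, two unmeasured -> could go either way
        p = MetabolicPanel(waist=95.0, triglycerides=1.8, sbp=118.0, dbp=74.0)
        assert classify_mets_idf(p, "male") is MetsStatus.INDETERMINATE
        # not obese: verdict negative regardless of missing components
        p2 = MetabolicPanel(waist=85.0, triglycerides=None, hdl=None)
        assert classify_mets_idf(p2, "male") is MetsStatus.NEGATIVE
        # obesity unknown but at most one component can be positive -> negative
        p3 = MetabolicPanel(triglycerides=1.8, hdl=1.4, sbp=118.0, dbp=74.0,
                            fasting_glucose=4.9)
        assert classify_mets_idf(p3, "male") is MetsStatus.NEGATIVE

    def test_non_positive_measurement_rejected(self):
        with pytest.raises(InputError):
            MetabolicPanel(hdl=-0.5)
        with pytest.raises(InputError):
            MetabolicPanel(sbp=110.0, dbp=115.0)

    def test_brute_force_grid_oracle(self):
        """Exhaustive check against a direct re-statement of the rule on a
        grid straddling every cut-off (complete panels, male)."""
        waists = [93.9, 94.0]
        tgs = [1.69, 1.7]
        hdls = [1.02, 1.03]
        sbps = [129.0, 130.0]
        glus = [5.59, 5.6]
        for w, t, h, s, g in itertools.product(waists, tgs, hdls, sbps, glus):
            p = MetabolicPanel(
                bmi=24.0, waist=w, sbp=s, dbp=70.0, triglycerides=t, hdl=h,
                fasting_glucose=g,
            )
            obese = w >= 94.0
            n_comp = sum([t >= 1.7, h < 1.03, s >= 130.0 or 70.0 >= 85.0, g >= 5.6])
            expected = (
                MetsStatus.POSITIVE if obese and n_comp >= 2 else MetsStatus.NEGATIVE
            )
            assert classify_mets_idf(p, "male") is expected, (w, t, h, s, g)


class TestEligibility:
    def test_exclusion_reasons_and_order(self, record_factory):
        records = [
            record_factory(id="ok"),
            record_factory(id="too_old", age=36.0),
            record_factory(id="late_baseline", baseline_offset_days=101),
            record_factory(id="short_followup", followup_years=0.5),
            record_factory(
                id="baseline_mets",
                waist=100.0,
                triglycerides=2.0,
                hdl=0.9,
            ),
        ]
        report = apply_eligibility(records)
        assert report.included == ["ok"]
        reasons = dict(report.excluded)
        assert reasons["too_old"] == "age_16_35"
        assert reasons["late_baseline"] == "baseline_within_100_days"
        assert reasons["short_followup"] == "followup_1_to_6_years"
        assert reasons["baseline_mets"] == "no_baseline_mets"
        assert sum(report.counts.values()) == report.n_excluded

    def test_boundary_inclusive(self, record_factory):
        # ±100 days inclusive; age bounds inclusive; follow-up [1, 6] inclusive
        records = [
            record_factory(id="a", baseline_offset_days=100),
            record_factory(id="b", baseline_offset_days=-100),
            record_factory(id="c", age=16.0),
            record_factory(id="d", age=35.0),
            record_factory(id="e", followup_years=1.0),
            record_factory(id="f", followup_years=6.0),
        ]
        assert apply_eligibility(records).n_excluded == 0

    def test_empty_input(self):
        report = apply_eligibility([])
        assert report.included == [] and report.excluded == []
        assert sum(report.counts.values()) == 0

    def test_idempotent(self, record_factory):
        records = [record_factory(id=f"P{i}", age=20 + i) for i in range(5)] + [
            record_factory(id="bad", age=40.0)
        ]
        first = apply_eligibility(records)
        survivors = [r for r in records if r.id in set(first.included)]
        second = apply_eligibility(survivors)
        assert second.included == first.included
        assert second.n_excluded == 0

    def test_service_criterion(self, record_factory):
        report = apply_eligibility([record_factory(id="x", treated_by_service=False)])
        assert dict(report.excluded)["x"] == "treated_by_service"


def test_cohort_frame_round_trip(record_factory):
    records = [record_factory(id=f"P{i}", bmi=20.0 + i) for i in range(4)]
    frame = records_to_frame(records)
    back = frame_to_records(frame)
    assert [r.id for r in back] == [r.id for r in records]
    assert all(
        back[i].baseline.get("bmi") == records[i].baseline.get("bmi")
        for i in range(4)
    )
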