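"""Performance metrics against independent oracles and closed forms."""

import math

import numpy as np
import pytest
from scipy.special import expit

from metsrisk.errors import (
    DegenerateFitError,
    InputError,
    UndefinedMetricError,
)
from metsrisk.metrics import (
    bootstrap_ci,
    brier_score,
    c_statistic,
    calibration_deciles,
    calibration_fit,
    compute_validation_report,
    nagelkerke_r2,
    vif,
)


def c_statistic_all_pairs(risks, outcomes):
    """O(n²) oracle: concordant + half-credit ties over all case/non-case pairs."""
    risks = np.asarray(risks, float)
    outcomes = np.asarray(outcomes, int)
    cases = risks[outcomes == 1]
    controls = risks[outcomes == 0]
    total = concordant = tied = 0
    for c in cases:
        for d in controls:
            total += 1
            if c > d:
                concordant += 1
            elif c == d:
                tied += 1
    return (concordant + 0.5 * tied) / total


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert c_statistic([0.3] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_worked_example_five_sixths(self):
        # 6 case/non-case pairs, 5 concordant
        assert c_statistic([0.8, 0.6, 0.4, 0.3, 0.2], [1, 0, 1, 0, 0]) == pytest.approx(5 / 6)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            c_statistic([0.2, 0.4], [1, 1])

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(5, 120)
            risks = rng.random(n).round(1)  # coarse grid forces ties
            outcomes = rng.integers(0, 2, n)
            if outcomes.min() == outcomes.max():
                continue
            assert c_statistic(risks, outcomes) == pytest.approx(
                c_statistic_all_pairs(risks, outcomes), abs=1e-12
            )

    def test_monotone_invariance_and_reversal(self):
        rng = np.random.default_rng(7)
        risks = rng.random(50)
        outcomes = rng.integers(0, 2, 50)
        c = c_statistic(risks, outcomes)
        assert c_statistic(expit(5 * risks - 2), outcomes) == pytest.approx(c)
        assert c_statistic(-risks, outcomes) == pytest.approx(1 - c)


class TestBrier:
    def test_perfect_predictions(self):
        assert brier_score([1.0, 0.0], [1, 0]) == 0.0

    def test_constant_half_is_quarter(self):
        rng = np.random.default_rng(0)
        outcomes = rng.integers(0, 2, 40)
        assert brier_score([0.5] * 40, outcomes) == 0.25

    def test_worked_example(self):
        assert brier_score([0.8, 0.2], [1, 0]) == pytest.approx(0.04)

    def test_longhand_identity(self):
        # mean of p²(1-y) + (1-p)²y
        rng = np.random.default_rng(3)
        p = rng.random(30)
        y = rng.integers(0, 2, 30)
        longhand = np.mean(p**2 * (1 - y) + (1 - p) ** 2 * y)
        assert brier_score(p, y) == pytest.approx(longhand)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            brier_score([0.5], [1, 0])


class TestNagelkerke:
    def test_prevalence_risks_give_zero(self):
        y = np.array([1, 1, 0, 0, 0])
        assert nagelkerke_r2([0.4] * 5, y) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_longhand(self):
        # longhand: ll1 = 4·ln0.9, ll0 = 4·ln0.5, CS = 1-exp((ll0-ll1)/2),
        # max = 1-exp(ll0/2) = 0.75 -> ratio ≈ 0.92185
        y = [1, 1, 0, 0]
        r = [0.9, 0.9, 0.1, 0.1]
        ll1 = 4 * math.log(0.9)
        ll0 = 4 * math.log(0.5)
        expected = (1 - math.exp((2 / 4) * (ll0 - ll1))) / (1 - math.exp((2 / 4) * ll0))
        assert expected == pytest.approx(0.9218, abs=5e-4)
        assert nagelkerke_r2(r, y) == pytest.approx(expected, abs=1e-12)

    def test_near_perfect_approaches_one(self):
        y = [1, 1, 0, 0]
        assert nagelkerke_r2([1 - 1e-9, 1 - 1e-9, 1e-9, 1e-9], y) > 0.999

    def test_degenerate_risk_signal(self):
        with pytest.raises(DegenerateFitError):
            nagelkerke_r2([0.0, 1.0], [1, 0])

    def test_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(30)
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            assert 0 <= nagelkerke_r2(p, y) <= 1


class TestCalibrationFit:
    def test_self_consistent_simulation(self):
        # outcomes drawn from the linear predictor itself: intercept ~0, slope ~1
        rng = np.random.default_rng(11)
        n = 20000
        lp = rng.normal(-2.0, 1.0, n)
        y = (rng.random(n) < expit(lp)).astype(float)
        fit = calibration_fit(lp, y, "intercept_slope")
        assert fit.intercept == pytest.approx(0.0, abs=0.05)
        assert fit.slope == pytest.approx(1.0, abs=0.05)

    def test_offset_construction_recovers_shift(self):
        rng = np.random.default_rng(12)
        n = 20000
        lp = rng.normal(-2.0, 1.0, n)
        y = (rng.random(n) < expit(lp + 0.5)).astype(float)
        fit = calibration_fit(lp, y, "intercept_only")
        assert fit.slope == 1.0
        assert fit.intercept == pytest.approx(0.5, abs=0.05)

    def test_constant_lp_slope_undefined(self):
        with pytest.raises(DegenerateFitError):
            calibration_fit([1.0] * 10, [1, 0] * 5, "intercept_slope")

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            calibration_fit([0.1, 0.2], [1, 1], "intercept_only")


class TestCalibrationDeciles:
    def test_partition_sizes(self):
        rng = np.random.default_rng(1)
        bins = calibration_deciles(rng.random(20), rng.integers(0, 2, 20))
        assert [b.n for b in bins] == [2] * 10

    def test_remainder_goes_to_early_bins(self):
        rng = np.random.default_rng(2)
        bins = calibration_deciles(rng.random(23), rng.integers(0, 2, 23))
        assert [b.n for b in bins] == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_wilson_interval_contains_observed(self):
        rng = np.random.default_rng(3)
        bins = calibration_deciles(rng.random(57), rng.integers(0, 2, 57))
        for b in bins:
            assert b.ci_low <= b.observed_proportion <= b.ci_high

    def test_well_calibrated_simulation(self):
        rng = np.random.default_rng(4)
        n = 20000
        risks = rng.uniform(0.02, 0.5, n)
        y = (rng.random(n) < risks).astype(float)
        bins = calibration_deciles(risks, y)
        for b in bins:
            assert abs(b.observed_proportion - b.mean_predicted) < 0.03

    def test_all_tied_risks_still_partition(self):
        bins = calibration_deciles([0.3] * 25, [0, 1] * 12 + [0], groups=10)
        assert sum(b.n for b in bins) == 25

    def test_too_few_observations(self):
        with pytest.raises(InputError):
            calibration_deciles([0.5] * 5, [1, 0, 1, 0, 1], groups=10)


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        lo, hi = bootstrap_ci(lambda r, y: 3.14, [0.5] * 20, [1, 0] * 10, 200, seed=0)
        assert lo == hi == 3.14

    def test_same_seed_identical(self):
        rng = np.random.default_rng(9)
        r = rng.random(60)
        y = rng.integers(0, 2, 60)
        a = bootstrap_ci(c_statistic, r, y, 300, seed=123)
        b = bootstrap_ci(c_statistic, r, y, 300, seed=123)
        assert a == b

    def test_small_cohort_ci_brackets_large_sample_value(self, full_model):
        # simulated 116-person, ~13%-prevalence cohort: the bootstrap CI for
        # C should bracket the large-sample (population) C of the same model
        from metsrisk.cohort import analysis_frame
        from metsrisk.simulate import CohortSimConfig, generate_cohort

        big_cfg = CohortSimConfig(n=20000, seed=77, target_prevalence=0.13)
        recs, truth = generate_cohort(big_cfg)
        frame = analysis_frame(recs)
        risks_big = expit(full_model.linear_predictor_frame(frame) + truth.intercept_offset)
        c_large = c_statistic(risks_big, truth.outcomes)

        small_cfg = CohortSimConfig(n=116, seed=78, target_prevalence=0.13)
        recs_s, truth_s = generate_cohort(small_cfg)
        frame_s = analysis_frame(recs_s)
        risks_s = expit(
            full_model.linear_predictor_frame(frame_s) + truth_s.intercept_offset
        )
        lo, hi = bootstrap_ci(c_statistic, risks_s, truth_s.outcomes, 500, seed=5)
        assert lo <= c_large <= hi


class TestVIF:
    def test_orthogonal_columns_unity(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = rng.standard_normal((n, 3))
        report = vif(X)
        for v in report.vif.values():
            assert v == pytest.approx(1.0, abs=0.05)

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(1)
        n = 200000
        a = rng.standard_normal(n)
        b = 0.9 * a + math.sqrt(1 - 0.81) * rng.standard_normal(n)
        c = rng.standard_normal(n)
        report = vif(np.column_stack([a, b, c]))
        assert report.vif["0"] == pytest.approx(1 / (1 - 0.81), rel=0.02)
        assert report.vif["1"] == pytest.approx(1 / (1 - 0.81), rel=0.02)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(100)
        report = vif(np.column_stack([a, a, rng.standard_normal(100)]))
        assert math.isinf(report.vif["0"])


def test_validation_report_assembly():
    rng = np.random.default_rng(21)
    n = 300
    lp = rng.normal(-2, 1, n)
    y = (rng.random(n) < expit(lp)).astype(float)
    report = compute_validation_report(expit(lp), lp, y, bootstrap_replicates=200, seed=0)
    assert report.n == n and report.n_events == int(y.sum())
    assert sum(b.n for b in report.decile_table) == n
    assert report.c_statistic.ci_low <= report.c_statistic.estimate <= report.c_statistic.ci_high
    frame = report.to_frame()
    assert set(frame["metric"]) == {
        "c_statistic",
        "r2_nagelkerke",
        "brier",
        "cal_intercept",
        "cal_slope",
    }
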