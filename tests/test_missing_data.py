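"""Chained-equations imputation and Rubin's-rules pooling."""

import numpy as np
import pandas as pd
import pytest

from metsrisk.errors import AnalysisError, CannotImputeError, InputError
from metsrisk.missing_data import (
    impute_chained,
    per_imputation_outputs,
    pool_rubin,
    pool_transformed,
)


@pytest.fixture
def complete_frame():
    rng = np.random.default_rng(0)
    n = 300
    x = rng.normal(0, 1, n)
    z = 0.5 * x + rng.normal(0, 1, n)
    y = (rng.random(n) < 0.3).astype(float)
    return pd.DataFrame({"x": x, "z": z, "y": y})


class TestImputeChained:
    def test_no_missing_returns_identical_copies(self, complete_frame):
        result = impute_chained(complete_frame, m=3, iterations=2, seed=0)
        assert result.m == 3
        for table in result.imputations:
            pd.testing.assert_frame_equal(table, complete_frame)

    def test_deterministic_given_seed(self, complete_frame):
        holed = complete_frame.copy()
        holed.loc[::5, "z"] = np.nan
        a = impute_chained(holed, m=2, iterations=3, seed=42)
        b = impute_chained(holed, m=2, iterations=3, seed=42)
        for ta, tb in zip(a.imputations, b.imputations):
            pd.testing.assert_frame_equal(ta, tb)

    def test_observed_cells_unchanged_and_holes_filled(self, complete_frame):
        holed = complete_frame.copy()
        mask = np.zeros(len(holed), dtype=bool)
        mask[::4] = True
        holed.loc[mask, "z"] = np.nan
        result = impute_chained(holed, m=2, iterations=2, seed=1)
        for table in result.imputations:
            assert not table["z"].isna().any()
            np.testing.assert_allclose(
                table.loc[~mask, "z"], complete_frame.loc[~mask, "z"]
            )
        assert result.missingness_map["z"] == pytest.approx(mask.mean())

    def test_chains_differ(self, complete_frame):
        holed = complete_frame.copy()
        holed.loc[::4, "z"] = np.nan
        result = impute_chained(holed, m=2, iterations=2, seed=3)
        a, b = result.imputations
        assert (a["z"] != b["z"]).any()

    def test_fully_missing_column_rejected(self, complete_frame):
        holed = complete_frame.copy()
        holed["z"] = np.nan
        with pytest.raises(CannotImputeError):
            impute_chained(holed, m=2, iterations=2, seed=0)

    def test_mcar_mean_recovery(self):
        # 20% MCAR holes: pooled mean must sit inside the complete-data CI
        from metsrisk.cohort import analysis_frame
        from metsrisk.simulate import CohortSimConfig, generate_cohort, inject_missingness

        cfg = CohortSimConfig(n=5000, seed=10, target_prevalence=None, missingness=None)
        records, _ = generate_cohort(cfg)
        frame = analysis_frame(records).drop(columns=["id"])
        n = len(frame)
        complete_mean = frame["hdl"].mean()
        half_width = 1.96 * frame["hdl"].std() / np.sqrt(n)
        holed, mask = inject_missingness(frame, {"hdl": 0.2}, seed=11)
        assert mask["hdl"].mean() == pytest.approx(0.2, abs=0.02)
        result = impute_chained(holed, m=5, iterations=5, seed=12)
        means = [t["hdl"].mean() for t in result.imputations]
        vars_ = [t["hdl"].var(ddof=1) / n for t in result.imputations]
        pooled = pool_rubin(means, vars_)
        assert abs(pooled.estimate - complete_mean) < half_width

    def test_serialization_round_trip(self, complete_frame, tmp_path):
        holed = complete_frame.copy()
        holed.loc[::4, "z"] = np.nan
        result = impute_chained(holed, m=2, iterations=2, seed=5)
        outdir = result.to_directory(tmp_path / "imps")
        assert (outdir / "manifest.json").exists()
        back = pd.read_csv(outdir / "imputation_00.csv")
        np.testing.assert_allclose(back["z"], result.imputations[0]["z"])


class TestPoolRubin:
    def test_worked_example(self):
        pooled = pool_rubin([0.70, 0.72, 0.74], [0.01, 0.01, 0.01])
        assert pooled.estimate == pytest.approx(0.72)
        assert pooled.within_var == pytest.approx(0.01)
        assert pooled.between_var == pytest.approx(0.0004)
        assert pooled.total_var == pytest.approx(0.01 + (4 / 3) * 0.0004)
        assert pooled.total_var == pytest.approx(0.010533, abs=1e-6)

    def test_total_variance_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            m = rng.integers(2, 12)
            q = rng.normal(0, 1, m)
            u = rng.random(m)
            p = pool_rubin(q, u)
            assert p.total_var == pytest.approx(
                p.within_var + (1 + 1 / m) * p.between_var
            )
            assert p.total_var >= p.within_var

    def test_identical_estimates_no_between_variance(self):
        p = pool_rubin([0.5, 0.5, 0.5], [0.02, 0.02, 0.02])
        assert p.between_var == 0.0
        assert p.total_var == p.within_var

    def test_single_imputation_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            p = pool_rubin([0.6], [0.01])
        assert p.estimate == 0.6
        assert p.total_var == 0.01

    def test_empty_input(self):
        with pytest.raises(InputError):
            pool_rubin([], [])

    def test_barnard_rubin_df_smaller_than_classical(self):
        classical = pool_rubin([0.6, 0.7, 0.65], [0.01, 0.01, 0.01])
        adjusted = pool_rubin([0.6, 0.7, 0.65], [0.01, 0.01, 0.01], df_com=100)
        assert adjusted.df < classical.df

    def test_logit_pooling_respects_bounds(self):
        # near-boundary C-statistics: naive pooling CI can exceed 1
        p = pool_transformed([0.95, 0.97, 0.99], [0.002, 0.002, 0.002])
        assert 0 < p.ci_low < p.estimate < p.ci_high < 1


class TestPerImputation:
    def test_cardinality_and_representative(self, complete_frame):
        result = impute_chained(complete_frame, m=5, iterations=1, seed=0)
        outputs = per_imputation_outputs(result, lambda df: df["x"].mean(), seed=7)
        assert len(outputs.results) == 5
        assert 0 <= outputs.representative_index < 5
        again = per_imputation_outputs(result, lambda df: df["x"].mean(), seed=7)
        assert again.representative_index == outputs.representative_index

    def test_analysis_failure_aggregated_with_index(self, complete_frame):
        result = impute_chained(complete_frame, m=3, iterations=1, seed=0)
        calls = {"n": 0}

        def flaky(df):
            calls["n"] += 1
            if calls["n"] == 2:
                raise ValueError("boom")
            return 1.0

        with pytest.raises(AnalysisError) as err:
            per_imputation_outputs(result, flaky, seed=0)
        assert err.value.indices == (1,)

    def test_decile_tables_similar_across_imputations(self):
        from metsrisk.cohort import analysis_frame
        from metsrisk.metrics import calibration_deciles
        from metsrisk.simulate import (
            CohortSimConfig,
            default_true_model,
            generate_cohort,
            inject_missingness,
        )
        from scipy.special import expit

        model = default_true_model("full")
        cfg = CohortSimConfig(n=2000, seed=20, target_prevalence=None, missingness=None)
        records, _ = generate_cohort(cfg)
        frame = analysis_frame(records).drop(columns=["id"])
        y = frame["outcome"].to_numpy()
        holed, _ = inject_missingness(frame, {"hdl": 0.05}, seed=21)
        imputed = impute_chained(holed, m=3, iterations=3, seed=22)

        def deciles(df):
            risks = expit(model.linear_predictor_frame(df))
            return np.array(
                [b.observed_proportion for b in calibration_deciles(risks, y)]
            )

        outputs = per_imputation_outputs(imputed, deciles, seed=0)
        for other in outputs.results[1:]:
            assert np.max(np.abs(other - outputs.results[0])) < 0.05
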