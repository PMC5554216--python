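"""Sub-plot summarization: selection, censored imputation, median polish."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from siteocc.exceptions import DataError
from siteocc.summarize import (FeatureMatrix, build_feature_matrix,
                               impute_matrix, log_of_sum, median_polish,
                               select_features, summarize_form, tmp_summarize)

from conftest import make_dataset


def _fm(values, runs=None, features=None, conditions=None):
    values = np.asarray(values, dtype=float)
    runs = runs or [f"r{i+1}" for i in range(values.shape[0])]
    features = features or [f"f{j+1}" for j in range(values.shape[1])]
    conditions = conditions or {r: "A" for r in runs}
    return FeatureMatrix("S", "form", pd.DataFrame(values, index=runs,
                                                   columns=features), conditions)


class TestSelectFeatures:
    def test_low_coverage_feature_dropped(self):
        vals = np.ones((6, 3))
        vals[1:, 2] = np.nan                      # feature 3 seen in 1/6 runs
        out = select_features(_fm(vals), min_coverage=0.5)
        assert list(out.values.columns) == ["f1", "f2"]

    def test_identity_when_fully_observed(self):
        out = select_features(_fm(np.ones((4, 3))))
        assert list(out.values.columns) == ["f1", "f2", "f3"]

    def test_fallback_keeps_single_best_feature(self):
        vals = np.full((6, 2), np.nan)
        vals[0, 0] = 10.0
        vals[0, 1] = 12.0
        vals[1, 1] = 12.0                          # f2 better covered
        out = select_features(_fm(vals), min_coverage=0.9)
        assert list(out.values.columns) == ["f2"]

    def test_deterministic_under_column_permutation(self):
        vals = np.array([[1.0, 2.0, np.nan], [1.0, np.nan, 3.0],
                         [1.0, 2.0, 3.0], [1.0, 2.0, np.nan]])
        a = select_features(_fm(vals, features=["x", "y", "z"]))
        b = select_features(_fm(vals[:, ::-1], features=["z", "y", "x"]))
        assert list(a.values.columns) == list(b.values.columns)


class TestImputeCensored:
    def test_no_missing_is_identity(self):
        vals = np.arange(6.0).reshape(2, 3) + 20
        filled, mask = impute_matrix(pd.DataFrame(vals))
        np.testing.assert_array_equal(filled.to_numpy(), vals)
        assert not mask.to_numpy().any()

    def test_imputed_at_most_censoring_limit_and_observed_unchanged(self):
        df = pd.DataFrame([[20.0, 21.0, 19.5], [20.2, np.nan, 19.6]],
                          index=["r1", "r2"], columns=["f1", "f2", "f3"])
        filled, mask = impute_matrix(df, limit_factor=1.0)
        limit = 21.0                               # min observed of f2
        assert filled.loc["r2", "f2"] <= limit + 1e-9
        assert mask.loc["r2", "f2"]
        obs = df.notna()
        np.testing.assert_array_equal(filled.to_numpy()[obs.to_numpy()],
                                      df.to_numpy()[obs.to_numpy()])

    def test_matches_independent_likelihood_maximizer(self):
        # independent oracle: same censored-normal additive model, but
        # maximized by differential evolution over an explicit NLL
        df = pd.DataFrame([[20.0, 21.0, 19.5], [20.3, np.nan, 19.9]],
                          index=["r1", "r2"], columns=["f1", "f2", "f3"])
        limit = 21.0

        def oracle_nll(theta):
            mu0, a2, b2, b3, log_s = theta
            s = math.exp(log_s)
            pred = np.array([[mu0, mu0 + b2, mu0 + b3],
                             [mu0 + a2, mu0 + a2 + b2, mu0 + a2 + b3]])
            ll = stats.norm.logpdf(
                [20.0, 21.0, 19.5, 20.3, 19.9],
                loc=[pred[0, 0], pred[0, 1], pred[0, 2], pred[1, 0], pred[1, 2]],
                scale=s).sum()
            ll += stats.norm.logcdf((limit - pred[1, 1]) / s)
            return -ll

        res = optimize.differential_evolution(
            oracle_nll, [(15, 25), (-2, 2), (-2, 2), (-2, 2), (-6, 1)],
            seed=0, tol=1e-10, polish=True)
        mu0, a2, b2, _, _ = res.x
        oracle_pred = min(mu0 + a2 + b2, limit)

        filled, _ = impute_matrix(df, limit_factor=1.0)
        assert filled.loc["r2", "f2"] == pytest.approx(oracle_pred, abs=1e-3)

    def test_fully_missing_run_left_unsummarized(self):
        vals = np.array([[20.0, 21.0], [np.nan, np.nan], [20.4, 21.2]])
        fm = _fm(vals)
        filled, _ = impute_matrix(fm.values)
        assert filled.iloc[1].isna().all()
        fm2 = FeatureMatrix("S", "form", filled, fm.conditions)
        out = tmp_summarize(fm2)
        assert set(out["run_id"]) == {"r1", "r3"}

    def test_never_observed_feature_dropped_dead_run_kept_missing(self):
        df = pd.DataFrame([[20.0, np.nan], [np.nan, np.nan]],
                          index=["r1", "r2"], columns=["f1", "f2"])
        filled, mask = impute_matrix(df)
        assert list(filled.columns) == ["f1"]      # f2 never observed
        assert np.isnan(filled.loc["r2", "f1"])    # fully censored run stays NaN
        assert not mask.to_numpy().any()


class TestMedianPolish:
    def test_exactly_additive_2x2(self):
        fm = _fm([[10.0, 12.0], [11.0, 13.0]])
        out = tmp_summarize(fm)
        np.testing.assert_allclose(out["log2_summary"], [11.0, 12.0])

    def test_single_feature_returns_its_values(self):
        fm = _fm([[10.0], [11.5], [9.0]])
        out = tmp_summarize(fm)
        np.testing.assert_allclose(out["log2_summary"], [10.0, 11.5, 9.0])

    def test_resistant_to_single_outlier(self):
        base = np.add.outer([10.0, 11.0, 12.0], [0.0, 1.0, 2.0])
        clean = tmp_summarize(_fm(base))["log2_summary"].to_numpy()
        spiked = base.copy()
        spiked[0, 2] += 5.0
        out = tmp_summarize(_fm(spiked))["log2_summary"].to_numpy()
        np.testing.assert_allclose(out, clean, atol=1e-9)

    def test_additive_matrix_zero_residuals(self):
        x = np.add.outer([3.0, 5.0, 4.0, 7.0], [0.0, -1.0, 2.0])
        *_, resid = median_polish(x)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.floats(-50, 50), min_size=3, max_size=3),
                    min_size=3, max_size=5),
           st.floats(-10, 10))
    def test_constant_shift_moves_all_summaries(self, rows, c):
        x = np.array(rows)
        a = tmp_summarize(_fm(x))["log2_summary"].to_numpy()
        b = tmp_summarize(_fm(x + c))["log2_summary"].to_numpy()
        np.testing.assert_allclose(b, a + c, atol=1e-5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.floats(-50, 50), min_size=4, max_size=4),
                    min_size=4, max_size=4),
           st.permutations(range(4)))
    def test_invariant_to_run_and_feature_permutation(self, rows, perm):
        x = np.array(rows)
        runs = [f"r{i}" for i in range(4)]
        base = tmp_summarize(_fm(x, runs=runs)).set_index("run_id")["log2_summary"]
        permuted = tmp_summarize(
            _fm(x[list(perm)][:, list(perm)],
                runs=[runs[i] for i in perm],
                features=[f"f{j+1}" for j in perm])
        ).set_index("run_id")["log2_summary"]
        np.testing.assert_allclose(permuted.sort_index(), base.sort_index(),
                                   atol=1e-5)


class TestSummarizeForm:
    def _ds(self):
        rows = []
        for run in ("r1", "r2"):
            rows += [("S", "PEP", "unmodified", 2, 0, run, 1.0),
                     ("S", "PEP", "unmodified", 2, 1, run, 19.0)]
        return make_dataset(rows, {"r1": "A", "r2": "A"})

    def test_log_of_sum_adds_raw_areas(self):
        out = summarize_form(self._ds(), "S", "unmodified", method="logofsum")
        np.testing.assert_allclose(out["log2_summary"], np.log2(20.0))

    def test_constant_data_gives_constant_summaries(self):
        rows = [("S", "PEP", "unmodified", 2, i, run, 256.0)
                for i in range(3) for run in ("r1", "r2")]
        ds = make_dataset(rows, {"r1": "A", "r2": "A"})
        out = summarize_form(ds, "S", "unmodified")
        np.testing.assert_allclose(out["log2_summary"], 8.0)

    def test_tmp_pipeline_fills_missing_runs(self):
        # feature f2 unobserved in r2 -> imputed, both runs summarized
        rows = [("S", "PEP", "unmodified", 2, 0, "r1", 100.0),
                ("S", "PEP", "unmodified", 3, 0, "r1", 80.0),
                ("S", "PEP", "unmodified", 2, 0, "r2", 105.0)]
        ds = make_dataset(rows, {"r1": "A", "r2": "A"})
        out = summarize_form(ds, "S", "unmodified", min_coverage=0.5)
        assert set(out["run_id"]) == {"r1", "r2"}
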