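"""Kalman filtering, duplicate/imputation cleaning and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triboostcardio as tb
from triboostcardio.preprocessing import drop_zero_variance


class TestKalman:
    def test_constant_signal_convergence(self):
        """Estimate converges monotonically to a constant signal."""
        out = tb.kalman_filter_series(np.full(2000, 70.0), q=0.0, r=1e-3,
                                      init_estimate=71.0, init_cov=1.0)
        errs = np.abs(out - 70.0)
        assert np.all(np.diff(errs) <= 1e-15)
        assert errs[-1] < 1e-6

    def test_perfect_measurement_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(80, 10, 500)
        out = tb.kalman_filter_series(x, q=0.01, r=1e-12)
        assert np.allclose(out, x, atol=1e-4)

    def test_iid_noise_estimate_and_gain_oracle(self):
        """q=0 on i.i.d. noise: the filter reduces to recursive averaging.

        Final estimate within 3*sigma/sqrt(n) of the mean; the n-th gain
        equals the closed-form P0/(r + n*P0).
        """
        rng = np.random.default_rng(1)
        sigma, c, n = 2.0, 65.0, 10_000
        x = rng.normal(c, sigma, n)
        out, gains = tb.kalman_filter_series(x, q=0.0, r=sigma**2,
                                             init_estimate=0.0, init_cov=1.0,
                                             return_gains=True)
        assert abs(out[-1] - c) < 3 * sigma / np.sqrt(n) + abs(c) / (1 + n / sigma**2)
        assert gains[-1] == pytest.approx(1.0 / (sigma**2 + n), rel=1e-9)

    def test_steady_state_gain_matches_riccati_solution(self):
        q, r = 0.05, 4.0
        _, gains = tb.kalman_filter_series(np.zeros(500), q=q, r=r,
                                           init_estimate=0.0, return_gains=True)
        assert gains[-1] == pytest.approx(tb.kalman_steady_state_gain(q, r), abs=1e-9)

    def test_missing_entries_get_prediction_only(self):
        x = np.array([1.0, np.nan, np.nan, 1.0])
        out = tb.kalman_filter_series(x, q=0.0, r=1.0, init_estimate=1.0)
        assert out.shape == x.shape
        assert out[1] == out[0]  # no correction on missing steps

    def test_variance_reduction_over_seeds(self):
        """Filtered variance <= raw variance on stationary noise, 20 seeds."""
        for s in range(20):
            rng = np.random.default_rng(s)
            x = rng.normal(100, 8, 400)
            out = tb.kalman_filter_series(x, q=0.0, r=64.0)
            assert np.var(out) <= np.var(x)

    def test_determinism_and_errors(self):
        x = np.arange(10.0)
        assert np.array_equal(tb.kalman_filter_series(x), tb.kalman_filter_series(x))
        with pytest.raises(ValueError):
            tb.kalman_filter_series(x, r=0.0)
        with pytest.raises(ValueError):
            tb.kalman_filter_series(np.full(5, np.nan))
        with pytest.raises(ValueError):
            tb.kalman_filter_series(np.array([]))


class TestTableCleaning:
    def test_drop_duplicates_keeps_first(self):
        df = pd.DataFrame({"a": [1, 1, 2, 2], "b": [0, 0, 1, 1],
                           "target": [0, 1, 1, 1]})
        out = tb.drop_duplicates(df)
        assert len(out) == 2
        assert out["target"].tolist() == [0, 1]  # first occurrences survive

    def test_drop_duplicates_identity_and_boundary(self):
        df = pd.DataFrame({"a": [1, 2, 3]})
        pd.testing.assert_frame_equal(tb.drop_duplicates(df), df)
        allsame = pd.DataFrame({"a": [5] * 10})
        assert len(tb.drop_duplicates(allsame)) == 1

    def test_impute_mean_and_median(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        assert tb.impute_missing(df, "mean")["a"].tolist() == [1.0, 2.0, 3.0]
        df2 = pd.DataFrame({"a": [1.0, np.nan, 3.0, 100.0]})
        assert tb.impute_missing(df2, "median")["a"][1] == 3.0

    def test_impute_mode_for_categorical_and_errors(self):
        df = pd.DataFrame({"c": ["x", None, "x", "y"]})
        assert tb.impute_missing(df)["c"].tolist() == ["x", "x", "x", "y"]
        with pytest.raises(ValueError):
            tb.impute_missing(pd.DataFrame({"a": [np.nan, np.nan]}))
        with pytest.raises(ValueError):
            tb.impute_missing(pd.DataFrame({"a": [1.0]}), strategy="mode")

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_imputation_conserves_observed(self, vals):
        arr = np.array(vals)
        arr[::3] = np.nan
        if np.isnan(arr).all():
            return
        df = pd.DataFrame({"a": arr})
        out = tb.impute_missing(df, "mean")
        obs = ~np.isnan(arr)
        assert np.array_equal(out["a"].to_numpy()[obs], arr[obs])
        assert not out["a"].isna().any()

    def test_zero_variance_columns_dropped(self):
        df = pd.DataFrame({"a": [1, 1, 1], "b": [1, 2, 3], "target": [0, 1, 0]})
        out = drop_zero_variance(df)
        assert list(out.columns) == ["b", "target"]


class TestHeartRateFlag:
    def test_default_rule_band(self):
        assert tb.flag_heart_rate(80, 40) is False   # mid-normal resting rate
        assert tb.flag_heart_rate(55, 30) is True    # below bradycardia bound
        assert tb.flag_heart_rate(55, 70) is True
        assert tb.flag_heart_rate(185, 40) is True   # above 220 - 40 = 180

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            tb.flag_heart_rate(0, 40)
        with pytest.raises(ValueError):
            tb.flag_heart_rate(80, 130)
        rule = tb.HeartRateRule(lower_bpm=50, upper_rule=lambda a: 200.0)
        assert tb.flag_heart_rate(55, 40, rule) is False


class TestMinMax:
    def test_printed_bp_range_maps_to_unit_interval(self):
        df = pd.DataFrame({"resting_bp": [94.0, 147.0, 200.0]})
        params = tb.fit_minmax(df)
        out = tb.apply_minmax(df, params)
        assert out["resting_bp"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_and_extrapolation(self):
        params = tb.fit_minmax(pd.DataFrame({"a": [3.0, 3.0], "b": [0.0, 10.0]}))
        out = tb.apply_minmax(pd.DataFrame({"a": [3.0], "b": [20.0]}), params)
        assert out["a"][0] == 0.0
        assert out["b"][0] == 2.0  # linear extrapolation, no clipping

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, vals):
        df = pd.DataFrame({"a": np.array(vals, dtype=float)})
        params = tb.fit_minmax(df)
        back = tb.invert_minmax(tb.apply_minmax(df, params), params)
        if df["a"].nunique() == 1:
            assert np.allclose(back["a"], df["a"].min())
        else:
            assert np.allclose(back["a"], df["a"], atol=1e-9 * max(1, abs(df["a"]).max()))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            tb.fit_minmax(pd.DataFrame({"a": []}))


def test_preprocess_table_end_to_end(small_cohort):
    noisy = small_cohort.copy()
    noisy.loc[0, "resting_bp"] = np.nan
    noisy = pd.concat([noisy, noisy.iloc[[1]]], ignore_index=True)
    out = tb.preprocess_table(noisy)
    assert len(out) == len(small_cohort)  # duplicate dropped
    assert not out.drop(columns="target").isna().any().any()
    assert "hr_flag" in out.columns
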