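"""Counterfactual prediction, annual incidence ratios and bootstrap inference."""

import numpy as np
import pandas as pd
import pytest

from itscount.model import fit_negative_binomial, select_by_aic
from itscount.ratios import (air_inference, annual_ratios, incidence_ratio_table,
                             predict_expected, results_frame)
from itscount.series import MonthlyCountSeries
from itscount.simulate import simulate_monthly_counts, true_means

from conftest import POPULATION, default_params, default_scenario


@pytest.fixture(scope="module")
def fitted():
    """One simulated series with its selected model and constant offset."""
    params = default_params(effect_by_year={2020: 1.5, 2021: 2.0, 2022: 2.5})
    series = simulate_monthly_counts(params, default_scenario(seed=17))
    offset = np.full(84, POPULATION)
    model = select_by_aic(series, offset[:48])
    return params, series, offset, model


def series_from_counts(pre_counts, post_counts, start_year=2016):
    counts = np.concatenate([pre_counts, post_counts])
    n = len(counts)
    df = pd.DataFrame({
        "month_index": np.arange(n),
        "year": start_year + np.arange(n) // 12,
        "month": np.arange(n) % 12 + 1,
        "count": counts,
        "period": ["pre"] * len(pre_counts) + ["post"] * len(post_counts),
    })
    return MonthlyCountSeries(subgroup="hand", data=df)


class TestPredictExpected:
    def test_in_sample_prediction_reproduces_fitted_means(self, fitted):
        _, series, offset, model = fitted
        pred = predict_expected(model, series.pre, offset[:48])
        assert np.allclose(pred, model.fitted_means(), rtol=1e-12)

    def test_flat_model_prediction_proportional_to_offset(self):
        counts = np.full(48, 120)
        series = series_from_counts(counts, [])
        offset = np.linspace(900.0, 1100.0, 48)
        scaled = 120 * offset / offset.mean()
        series.data["count"] = np.round(scaled).astype(int)
        model = fit_negative_binomial(series, 0, offset)
        # prediction over months with a doubled offset doubles the counts
        pred1 = predict_expected(model, series.data, offset)
        pred2 = predict_expected(model, series.data, 2 * offset)
        assert np.allclose(pred2, 2 * pred1)

    def test_misaligned_month_index_hard_error(self, fitted):
        _, series, offset, model = fitted
        shifted = series.post.copy()
        shifted["month_index"] = shifted["month_index"] + 1
        with pytest.raises(ValueError, match="mismatch"):
            predict_expected(model, shifted, offset[48:])

    def test_post_window_recovery_against_generative_truth(self):
        """Counterfactual extrapolation tracks the true no-effect means.

        At ~500-count months the mean absolute relative error of expected
        vs true mu over the 36 extrapolated months stays under 10%.
        """
        params = default_params(beta0=-8.5)  # ~490 visits/month
        scenario = default_scenario(seed=23)
        series = simulate_monthly_counts(params, scenario)
        offset = np.full(84, POPULATION)
        model = select_by_aic(series, offset[:48])
        pred = predict_expected(model, series.post, offset[48:])
        truth = true_means(params, scenario, with_effect=False)["mu"].to_numpy()[48:]
        mare = np.mean(np.abs(pred - truth) / truth)
        assert mare < 0.10


class TestAnnualRatios:
    def test_identity_when_observed_equals_expected(self):
        pre = np.full(48, 100)
        post = np.full(12, 100)
        s = series_from_counts(pre, post)
        table = annual_ratios(s, np.full(12, 100.0))
        assert table["aIR"].iloc[0] == pytest.approx(1.0)

    def test_doubled_observed_gives_air_two(self):
        s = series_from_counts(np.full(48, 100), np.full(12, 100))
        table = annual_ratios(s, np.full(12, 50.0))
        assert table["aIR"].iloc[0] == pytest.approx(2.0)

    def test_oir_hand_arithmetic(self):
        """Pre yearly totals {100,110,120,130}; 2020 observed 180 -> oIR = 180/115."""
        pre = np.concatenate([np.r_[[t - 11 * (t // 12)], np.full(11, t // 12)]
                              for t in (100, 110, 120, 130)])
        assert pre.sum() == 460 and len(pre) == 48
        post = np.r_[[180 - 11 * 15], np.full(11, 15)]
        s = series_from_counts(pre, post)
        table = annual_ratios(s, np.full(12, 150.0))
        assert table["oIR"].iloc[0] == pytest.approx(180 / 115)
        assert table["pre_annual_avg"].iloc[0] == pytest.approx(115.0)

    def test_rate_ratio_cancellation_asserted(self):
        s = series_from_counts(np.full(48, 100), np.full(12, 100))
        table = annual_ratios(s, np.full(12, 80.0), population_by_year={2020: 5e5})
        assert table["aIR"].iloc[0] == pytest.approx(100 * 12 / (80.0 * 12))

    def test_partial_year_refused(self):
        s = series_from_counts(np.full(48, 100), np.full(15, 100))
        with pytest.raises(ValueError, match="partial"):
            annual_ratios(s, np.full(15, 100.0))

    def test_zero_expected_rejected(self):
        s = series_from_counts(np.full(48, 100), np.full(12, 100))
        with pytest.raises(ValueError, match="not positive"):
            annual_ratios(s, np.zeros(12))


class TestAirInference:
    def test_replicate_count_consistency(self, fitted):
        """1,000 vs 10,000 replicates differ by no more than Monte-Carlo error."""
        _, series, offset, model = fitted
        months = series.post[series.post["year"] == 2020]
        obs = int(months["count"].sum())
        # pick an observed value inside the predictive distribution so the
        # p-value is away from 0 and the binomial error bound is meaningful
        obs_mid = int(model.fitted_means()[:12].sum())
        small = air_inference(model, obs_mid, months, offset[48:60],
                              replicates=1000, seed=1)
        big = air_inference(model, obs_mid, months, offset[48:60],
                            replicates=10_000, seed=1)
        mc_err = 3 * np.sqrt(0.25 / 1000) * 2  # doubled two-sided bound
        assert abs(small.p_value - big.p_value) <= mc_err

    def test_pvalue_ci_coherence(self, fitted):
        """p < 0.05 iff the 95% CI for observed/expected excludes 1."""
        _, series, offset, model = fitted
        months = series.post[series.post["year"] == 2020]
        center = model.fitted_means()[:12].sum()
        for factor in (0.6, 1.0, 1.8):
            obs = int(center * factor)
            inf = air_inference(model, obs, months, offset[48:60],
                                replicates=4000, seed=2)
            excludes_one = inf.ci_low > 1.0 or inf.ci_high < 1.0
            assert (inf.p_value < 0.05) == excludes_one, factor

    def test_extreme_tail_reported_as_bound(self, fitted):
        _, series, offset, model = fitted
        months = series.post[series.post["year"] == 2020]
        huge = int(model.fitted_means()[:12].sum() * 10)
        inf = air_inference(model, huge, months, offset[48:60],
                            replicates=1000, seed=3)
        assert inf.p_display == "<0.001"

    def test_minimum_replicates_enforced(self, fitted):
        _, series, offset, model = fitted
        months = series.post[series.post["year"] == 2020]
        with pytest.raises(ValueError, match="1000"):
            air_inference(model, 100, months, offset[48:60], replicates=100)

    def test_air_invariant_to_offset_rescaling(self, fitted):
        """aIR is a count ratio: scaling the population offset cancels."""
        params, series, offset, _ = fitted
        m1 = select_by_aic(series, offset[:48])
        m2 = select_by_aic(series, 7.0 * offset[:48])
        t1 = annual_ratios(series, predict_expected(m1, series.post, offset[48:]))
        t2 = annual_ratios(series, predict_expected(m2, series.post, 7.0 * offset[48:]))
        assert np.allclose(t1["aIR"], t2["aIR"], rtol=1e-4)


class TestFullTable:
    def test_table_rows_complete_and_reproducible(self, fitted):
        _, series, offset, model = fitted
        res = incidence_ratio_table(model, series, offset[48:], replicates=1000, seed=5)
        again = incidence_ratio_table(model, series, offset[48:], replicates=1000, seed=5)
        assert results_frame(res).equals(results_frame(again))
        df = results_frame(res)
        assert list(df["year"]) == [2020, 2021, 2022]
        assert ((df["ci_low"] <= df["aIR"]) & (df["aIR"] <= df["ci_high"])).all()
        # oIR recomputes exactly from the series
        pre_avg = series.pre["count"].sum() / 4
        obs_2021 = series.post.query("year == 2021")["count"].sum()
        assert df.query("year == 2021")["oIR"].iloc[0] == pytest.approx(obs_2021 / pre_avg)
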