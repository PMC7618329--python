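"""Death risk functions, AQHI scaling/categories, comparator AQIs."""

import numpy as np
import pandas as pd
import pytest

from aqhimix.errors import InvalidParameterError
from aqhimix.indices import (
    WHO_2021_SHORT_TERM,
    IndexSeries,
    MultiPollutantParams,
    SinglePollutantParams,
    aqhi_value,
    aqi_chn,
    aqi_eu,
    aqi_usa,
    categorize_aqhi,
    compute_aqhi,
    contribution_shares,
    drf_multi,
    drf_single,
    make_aqhi_scale,
    monthly_category_counts,
    usa_table_top,
)


def sp(pollutant, beta, country="X"):
    return SinglePollutantParams(country, pollutant, beta, 1e-8)


BETAS = [sp("pm25", 0.0008), sp("o3", 0.0004), sp("no2", 0.0012), sp("so2", 0.0006)]
MULTI = MultiPollutantParams("X", 0.0005, (0.25, 0.25, 0.25, 0.25))


class TestDRF:
    def test_zero_concentrations_give_zero(self):
        assert drf_single([0, 0, 0, 0], BETAS) == 0.0
        assert drf_multi([0, 0, 0, 0], MULTI) == 0.0

    def test_single_pollutant_exponential_form(self):
        out = drf_single([50, 0, 0, 0], [sp("pm25", 0.001)] + BETAS[1:])
        assert out == pytest.approx(100 * (np.exp(0.05) - 1), abs=1e-10)
        assert out == pytest.approx(5.1271, abs=1e-4)

    def test_single_is_additive_over_pollutants(self):
        x = [20.0, 80.0, 30.0, 10.0]
        total = drf_single(x, BETAS)
        parts = sum(
            drf_single([v if i == j else 0 for i, v in enumerate(x)], BETAS)
            for j in range(4)
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_multi_weighted_sum(self):
        out = drf_multi([20, 80, 30, 10], MultiPollutantParams("X", 0.0005, (0.25,) * 4))
        assert out == pytest.approx(0.0005 * 35.0, rel=1e-12)

    def test_multi_linear_in_concentrations(self):
        x = np.array([10.0, 40, 20, 5])
        assert drf_multi(3 * x, MULTI) == pytest.approx(3 * drf_multi(x, MULTI))

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            drf_multi([-1, 0, 0, 0], MULTI)

    def test_nonnegative_when_betas_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 200, 4)
            assert drf_single(x, BETAS) >= 0
            assert drf_multi(x, MULTI) >= 0


class TestAQHIScale:
    def test_anchor_value_is_exactly_three(self):
        scale = make_aqhi_scale(MULTI)
        x_who = [WHO_2021_SHORT_TERM[k] for k in ("pm25", "o3", "no2", "so2")]
        assert aqhi_value(drf_multi(x_who, MULTI), scale) == 3

    def test_anchor_invariant_to_slope_rescaling(self):
        doubled = MultiPollutantParams("X", 2 * MULTI.beta_c, MULTI.weights)
        s1, s2 = make_aqhi_scale(MULTI), make_aqhi_scale(doubled)
        assert s2.drf_at_who == pytest.approx(2 * s1.drf_at_who)
        x_who = [WHO_2021_SHORT_TERM[k] for k in ("pm25", "o3", "no2", "so2")]
        assert aqhi_value(drf_multi(x_who, doubled), s2) == 3

    def test_single_pollutant_anchor(self):
        scale = make_aqhi_scale(BETAS)
        x_who = [WHO_2021_SHORT_TERM[b.pollutant_id] for b in BETAS]
        assert aqhi_value(drf_single(x_who, BETAS), scale) == 3

    def test_zero_slope_rejected(self):
        degenerate = MultiPollutantParams("X", 0.0, MULTI.weights)
        with pytest.raises(InvalidParameterError):
            make_aqhi_scale(degenerate)

    def test_scaling_arithmetic(self):
        scale = make_aqhi_scale(MULTI)
        assert aqhi_value(0.0, scale) == 1                      # floor
        assert aqhi_value(scale.drf_at_who, scale) == 3         # anchor
        assert aqhi_value(scale.drf_at_who * 10 / 3, scale) == 10
        assert aqhi_value(scale.drf_at_who * 20 / 3, scale) == 20  # "10+" retained

    def test_nondecreasing_in_drf(self):
        scale = make_aqhi_scale(MULTI)
        drfs = np.linspace(0, 5 * scale.drf_at_who, 200)
        vals = aqhi_value(drfs, scale)
        assert np.all(np.diff(vals) >= 0)


class TestCategories:
    @pytest.mark.parametrize(
        "value,expected",
        [(1, "low"), (3, "low"), (4, "moderate"), (6, "moderate"),
         (7, "high"), (10, "high"), (11, "very high"), (25, "very high")],
    )
    def test_band_edges(self, value, expected):
        assert categorize_aqhi(value) == expected

    def test_below_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            categorize_aqhi(0)


class TestAQIUSA:
    def test_all_zeros(self):
        assert aqi_usa([0, 0, 0, 0]) == 0

    def test_table_nodes_reproduced(self):
        # PM2.5 breakpoints are in table (ug/m3) units directly
        assert aqi_usa([12.0, 0, 0, 0]) == 50
        assert aqi_usa([35.4, 0, 0, 0]) == 100
        assert aqi_usa([150.4, 0, 0, 0]) == 200

    def test_top_of_highest_interval_is_500(self):
        for k, idx in (("pm25", 0), ("no2", 2), ("so2", 3)):
            x = [0.0, 0, 0, 0]
            x[idx] = usa_table_top(k)
            assert aqi_usa(x) == 500

    def test_overall_is_max_of_subindices(self):
        assert aqi_usa([12.0, 0, 0, 0]) == 50
        # NO2 at a mid band should dominate a clean-PM day
        no2_ugm3 = 650 * 46.01 / 24.45   # 650 ppb -> AQI 201
        assert aqi_usa([12.0, 0, no2_ugm3, 0]) == 201

    def test_monotone_within_intervals(self):
        vals = [aqi_usa([c, 0, 0, 0]) for c in np.linspace(0, 500, 120)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_2024_dialect_differs_on_pm25(self):
        assert aqi_usa([9.0, 0, 0, 0], dialect="2024") == 50
        assert aqi_usa([9.0, 0, 0, 0], dialect="pre2024") < 50


class TestAQIEU:
    def test_cleanest_band(self):
        assert aqi_eu([5, 20, 10, 20]) == 1

    def test_above_all_thresholds_is_band_six(self):
        assert aqi_eu([900, 900, 1100, 1300]) == 6

    def test_worst_pollutant_sets_band(self):
        # NO2 at 100 ug/m3 is band 3; everything else band 1
        assert aqi_eu([5, 20, 100, 20]) == 3


class TestAQICHN:
    def test_all_zeros(self):
        assert aqi_chn([0, 0, 0, 0]) == 0

    def test_pm25_250_is_exactly_300(self):
        assert aqi_chn([250, 0, 0, 0]) == 300

    def test_interior_linear_interpolation(self):
        # oracle by hand: PM2.5 55 between nodes (35,50) and (75,100):
        # 50 + (55-35)/(75-35)*50 = 75
        assert aqi_chn([55, 0, 0, 0]) == 75
        # O3 130 between (100,50) and (160,100): 50 + 30/60*50 = 75
        assert aqi_chn([0, 130, 0, 0]) == 75

    def test_ceiling_rounding(self):
        # PM2.5 36: 50 + 1/40*50 = 51.25 -> 52 under the standard's rounding-up
        assert aqi_chn([36, 0, 0, 0]) == 52


class TestShares:
    def test_weights_mode(self):
        p = MultiPollutantParams("X", 0.001, (0.5, 0.3, 0.1, 0.1))
        assert np.allclose(contribution_shares(p), [50, 30, 10, 10])

    def test_concentration_weighted_shares(self):
        p = MultiPollutantParams("X", 0.001, (0.25,) * 4)
        x = np.tile([100.0, 10.0, 10.0, 10.0], (30, 1))
        shares = contribution_shares(p, x, mode="concentration_weighted")
        assert shares[0] == pytest.approx(100 * 10 / 13, abs=1e-9)

    def test_shares_sum_to_hundred(self):
        p = MultiPollutantParams("X", 0.001, (0.4, 0.3, 0.2, 0.1))
        assert contribution_shares(p).sum() == pytest.approx(100.0)
        x = np.random.default_rng(1).uniform(5, 80, (50, 4))
        assert contribution_shares(p, x, "concentration_weighted").sum() == pytest.approx(100.0)


class TestMonthlyCounts:
    def test_constant_low_index_counts_month_lengths(self):
        dates = pd.date_range("2018-01-01", "2019-12-31", freq="D")
        series = IndexSeries(dates, np.full(len(dates), 2), None)
        counts, slopes = monthly_category_counts(series)
        assert (counts.sum(axis=1).to_numpy() == dates.to_period("M").value_counts().sort_index().to_numpy()).all()
        assert (counts["low"] == counts.sum(axis=1)).all()
        # the only slope left is the 28-31 day month-length wobble
        assert abs(slopes["low"]) < 0.1

    def test_monotone_drift_raises_high_category_slope(self):
        scale_params = MultiPollutantParams("X", 0.001, (0.25,) * 4)
        scale = make_aqhi_scale(scale_params)
        dates = pd.date_range("2015-01-01", periods=4 * 365, freq="D")
        drf = np.linspace(0, 4 * scale.drf_at_who, len(dates))
        idx = compute_aqhi(drf, scale, dates)
        counts, slopes = monthly_category_counts(idx)
        assert slopes["high"] > 0
        assert slopes["low"] < 0
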