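"""First-stage city models: curves, lag structure, linear coefficients."""

import numpy as np
import pytest

from aqhimix.data import CityDailySeries
from aqhimix.dlnm import (
    ModelConfig,
    cumulative_exposure_response,
    fit_city_dlnm,
    lag_response,
    linear_beta_city,
)
from aqhimix.errors import DataTooSparseError, DegenerateBasisError
from aqhimix.simulate import SimulationConfig, generate_city


@pytest.fixture(scope="module")
def lag0_city():
    """10-year city whose deaths respond to PM2.5 at lag 0 only."""
    cfg = SimulationConfig(
        years=10, seed=314, effect_mode="per_pollutant",
        pollutant_betas=(8e-4, 0.0, 0.0, 0.0),
        lag_profile=(1.0, 0, 0, 0, 0, 0, 0, 0),
        city_mean_ranges=None, missing_rates=(0.0,) * 4,
        between_city_sd=0.0, weight_jitter_sd=0.0,
    )
    return generate_city(cfg, 0)


@pytest.fixture(scope="module")
def lag0_fit(lag0_city):
    return fit_city_dlnm(lag0_city, "pm25")


class TestCurves:
    def test_zero_at_reference_with_zero_width_ci(self, lag0_fit):
        out = cumulative_exposure_response(lag0_fit, np.array([0.0, 20.0]), reference=0.0)
        assert out["percent"][0] == 0.0
        assert out["lo"][0] == 0.0 and out["hi"][0] == 0.0

    def test_positive_coefficients_give_monotone_curve(self, lag0_fit):
        grid = np.linspace(0, 80, 40)
        out = cumulative_exposure_response(lag0_fit, grid)
        rr = out["log_rr"]
        if np.all(np.diff(rr) >= 0):            # estimated curve increasing
            assert np.all(np.diff(out["percent"]) >= 0)  # exp preserves order
        # percent and log-RR always agree in sign
        assert np.all(np.sign(out["percent"]) == np.sign(np.round(rr, 15)))

    def test_recovers_injected_lag0_effect_within_30pct(self, lag0_city, lag0_fit):
        # contrast of +10 ug/m3 placed inside the observed range, where the
        # spline is supported; the injected effect is log-linear at lag 0
        ref = float(np.nanpercentile(lag0_city.pm25, 25))
        out = cumulative_exposure_response(
            lag0_fit, np.array([ref + 10.0]), reference=ref
        )
        true_log_rr = 8e-4 * 10
        assert out["log_rr"][0] == pytest.approx(true_log_rr, rel=0.30)

    def test_extrapolated_reference_flagged_not_fatal(self, lag0_fit):
        hi = lag0_fit.concentration_range[1]
        out = cumulative_exposure_response(lag0_fit, np.array([10.0]), reference=hi + 50)
        assert out["extrapolated_reference"]


class TestLagResponse:
    def test_zero_contrast_gives_all_zero_lags(self, lag0_fit):
        out = lag_response(lag0_fit, at_concentration=30.0, reference=30.0)
        assert np.allclose(out["percent"], 0.0)

    def test_per_lag_log_rr_sums_to_cumulative(self, lag0_fit):
        per_lag = lag_response(lag0_fit, 40.0, 0.0)["log_rr"].sum()
        cumul = cumulative_exposure_response(lag0_fit, np.array([40.0]), 0.0)["log_rr"][0]
        assert per_lag == pytest.approx(cumul, abs=1e-10)

    def test_injected_lag0_effect_peaks_at_lag_zero(self, lag0_fit):
        out = lag_response(lag0_fit, 40.0, 0.0)
        assert np.argmax(out["log_rr"]) == 0


class TestLinearBeta:
    def test_recovers_ma3_effect_within_two_se(self):
        cfg = SimulationConfig(
            years=10, seed=99, effect_mode="per_pollutant",
            pollutant_betas=(5e-4, 0.0, 0.0, 0.0),
            lag_profile=(1 / 3, 1 / 3, 1 / 3, 0, 0, 0, 0, 0),
            city_mean_ranges=None, missing_rates=(0.0,) * 4,
        )
        city = generate_city(cfg, 0)
        b, v = linear_beta_city(city, "pm25")
        assert abs(b - 5e-4) < 2 * np.sqrt(v)

    def test_null_after_permutation(self, city_null_3yr):
        b, v = linear_beta_city(city_null_3yr, "pm25")
        assert abs(b) < 3 * np.sqrt(v)

    def test_doubling_concentrations_halves_slope(self, city_3yr):
        b1, _ = linear_beta_city(city_3yr, "pm25")
        doubled = CityDailySeries(
            city_id="x2", country_id=city_3yr.country_id, dates=city_3yr.dates,
            deaths=city_3yr.deaths, pm25=2 * city_3yr.pm25, o3=city_3yr.o3,
            no2=city_3yr.no2, so2=city_3yr.so2,
            temperature=city_3yr.temperature, humidity=city_3yr.humidity,
        )
        b2, _ = linear_beta_city(doubled, "pm25")
        assert b2 == pytest.approx(b1 / 2, rel=1e-6)


class TestSensitivityConfigurations:
    @pytest.mark.parametrize(
        "override",
        [dict(adjust_humidity=False), dict(adjust_holiday=True),
         dict(weather_ma_window=3), dict(weather_ma_window=21),
         dict(time_df_per_year=5), dict(time_df_per_year=9),
         dict(temp_df=3), dict(temp_df=7)],
    )
    def test_alternate_specifications_fit(self, city_3yr, override):
        """Every sensitivity-analysis model variant fits and stays close
        to the headline specification's estimate."""
        base, _ = linear_beta_city(city_3yr, "pm25")
        b, v = linear_beta_city(city_3yr, "pm25", ModelConfig(**override))
        assert np.isfinite(b) and v > 0
        assert abs(b - base) < 4 * np.sqrt(v)


class TestBiasAndCoverage:
    def test_linear_beta_bias_and_ci_coverage_across_cities(self):
        """Over 200 simulated cities the estimator is near-unbiased and its
        nominal 95% CI covers the truth at a compatible rate."""
        true_beta = 5e-4
        cfg = SimulationConfig(
            years=3, seed=2024, effect_mode="per_pollutant",
            pollutant_betas=(true_beta, 0.0, 0.0, 0.0),
            lag_profile=(1 / 3, 1 / 3, 1 / 3, 0, 0, 0, 0, 0),
            missing_rates=(0.0,) * 4,
        )
        est, se = [], []
        for i in range(200):
            city = generate_city(cfg, i)
            b, v = linear_beta_city(city, "pm25")
            est.append(b)
            se.append(np.sqrt(v))
        est, se = np.array(est), np.array(se)
        assert abs(est.mean() - true_beta) < 0.10 * true_beta
        covered = np.mean(np.abs(est - true_beta) < 1.96 * se)
        assert 0.90 <= covered <= 0.99


class TestErrors:
    def test_constant_pollutant_rejected(self, city_3yr):
        flat = CityDailySeries(
            city_id="flat", country_id="X", dates=city_3yr.dates,
            deaths=city_3yr.deaths, pm25=np.full(len(city_3yr), 20.0),
            o3=city_3yr.o3, no2=city_3yr.no2, so2=city_3yr.so2,
            temperature=city_3yr.temperature, humidity=city_3yr.humidity,
        )
        with pytest.raises(DegenerateBasisError):
            fit_city_dlnm(flat, "pm25")

    def test_too_few_complete_days_rejected(self, city_3yr):
        short = city_3yr.slice(0, 400)
        with pytest.raises(DataTooSparseError):
            fit_city_dlnm(short, "pm25", ModelConfig(min_rows_per_column=50))
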