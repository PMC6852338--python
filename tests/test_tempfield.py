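"""Hourly regression model and universal-kriging temperature surfaces."""

import numpy as np
import pandas as pd
import pytest

from biovocem import synth
from biovocem.raster import RasterGrid
from biovocem.tempfield import (HourlyTemperatureModel, StationRecord,
                                UniversalKriging, VariogramSpec,
                                fit_hourly_model, krige_hour,
                                monthly_mean_series, read_stations_csv,
                                write_stations_csv)


def make_station(temps, sid="S1", x=0.0, y=0.0, alt=3000.0,
                 start="2014-01-01"):
    idx = pd.date_range(start, periods=len(temps), freq="h")
    return StationRecord(station_id=sid, x=x, y=y, altitude=alt,
                         series=pd.Series(temps, index=idx))


class TestStationRecord:
    def test_duplicate_timestamps_rejected(self):
        idx = pd.DatetimeIndex(["2014-01-01", "2014-01-01"])
        with pytest.raises(ValueError, match="duplicate"):
            StationRecord("S", 0, 0, 3000, pd.Series([1.0, 2.0], index=idx))

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_station([10.0, 80.0, 12.0])


class TestHourlyModel:
    def test_exact_linear_data_recovered(self):
        # T(h, d) = 0.9 * x(d) + 2 exactly, with the daily summary x supplied
        days = 15
        x = np.linspace(8, 16, days)
        temps = np.repeat(0.9 * x + 2.0, 24)
        st = make_station(temps)
        dates = pd.date_range("2014-01-01", periods=days).date
        model = HourlyTemperatureModel().fit(
            [st], daily_summaries={"S1": pd.Series(x, index=dates)})
        coef = model.coef_["S1"]
        assert np.allclose(coef[:, 0], 0.9, atol=1e-9)
        assert np.allclose(coef[:, 1], 2.0, atol=1e-8)

    def test_constant_series_degenerate_regressor(self):
        st = make_station([12.0] * (24 * 12))
        model = HourlyTemperatureModel().fit([st])
        coef = model.coef_["S1"]
        assert np.allclose(coef[:, 0], 0.0)
        assert np.allclose(coef[:, 1], 12.0)

    def test_sinusoid_plus_noise_rmse_bounded(self):
        spec = synth.StationSpec(n_stations=1, noise_std=0.3,
                                 seasonal_amplitude=0.0, seed=8)
        st = synth.generate_station_series(spec, n_days=30)[0]
        model = fit_hourly_model([st])
        df = pd.DataFrame({"t": st.series})
        df["date"] = df.index.date
        daily = df.groupby("date")["t"].agg(["min", "max"])
        dm = (daily["min"] + daily["max"]) / 2.0
        errs = []
        for date, g in df.groupby("date"):
            pred = model.predict(st.station_id, dm.loc[date])
            obs = g["t"].to_numpy()[:24]
            errs.append(pred - obs)
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse < 2 * spec.noise_std

    def test_sparse_hour_slots_filled_from_neighbours(self):
        st = make_station(np.tile(np.linspace(5, 15, 24), 12) +
                          np.repeat(np.linspace(0, 4, 12), 24))
        # drop almost all observations at hour 3
        series = st.series[~((st.series.index.hour == 3) &
                             (st.series.index.day > 1))]
        st2 = StationRecord("S1", 0, 0, 3000, series)
        model = HourlyTemperatureModel().fit([st2])
        assert model.filled_hours_["S1"] == [3]
        assert np.all(np.isfinite(model.coef_["S1"]))

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError, match="10 days"):
            HourlyTemperatureModel().fit([make_station([10.0] * 48)])


class TestVariogramSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VariogramSpec(nugget=-1.0)
        with pytest.raises(ValueError):
            VariogramSpec(nugget=2.0, sill=1.0)
        with pytest.raises(ValueError):
            VariogramSpec(range_=0.0)
        with pytest.raises(ValueError):
            VariogramSpec(model="cubic")

    @pytest.mark.parametrize("model", ["spherical", "exponential",
                                       "gaussian", "linear"])
    def test_zero_at_origin_and_monotone(self, model):
        v = VariogramSpec(model=model, nugget=0.1, sill=1.0, range_=100.0)
        h = np.linspace(0, 300, 50)
        g = v(h)
        assert g[0] == 0.0
        assert np.all(np.diff(g[1:]) >= -1e-12)


def planar_stations(n=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 3000, (n, 2))
    y = 0.01 * X[:, 0] + 0.02 * X[:, 1] + 5.0
    return X, y


class TestKriging:
    def test_constant_field(self):
        X, _ = planar_stations()
        uk = UniversalKriging(drift="constant").fit(X, np.full(len(X), 12.0))
        like = RasterGrid(values=np.zeros((10, 10)), origin=(0, 3000),
                          pixel_size=300.0)
        assert np.allclose(uk.predict_grid(like).values, 12.0, atol=1e-8)

    def test_planar_field_reproduced_under_linear_drift(self):
        X, y = planar_stations()
        uk = UniversalKriging(drift="linear", nugget=0.0).fit(X, y)
        like = RasterGrid(values=np.zeros((25, 25)), origin=(0, 3000),
                          pixel_size=120.0)
        out = uk.predict_grid(like)
        gx, gy = like.cell_centers()
        assert np.abs(out.values - (0.01 * gx + 0.02 * gy + 5.0)).max() < 1e-3

    def test_exact_at_stations_with_zero_nugget(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1000, (8, 2))
        y = 10 + np.sin(X[:, 0] / 200) + 0.5 * rng.standard_normal(8)
        uk = UniversalKriging(nugget=0.0).fit(X, y)
        assert np.abs(uk.predict(X) - y).max() < 1e-6

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1000, (9, 2))
        y = rng.uniform(8, 15, 9)
        uk = UniversalKriging().fit(X, y)
        pts = rng.uniform(0, 1000, (20, 2))
        assert np.allclose(uk.weights(pts).sum(axis=0), 1.0, atol=1e-8)

    def test_constant_shift_passes_through(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1000, (10, 2))
        y = rng.uniform(8, 15, 10)
        pts = rng.uniform(0, 1000, (15, 2))
        base = UniversalKriging(variogram=VariogramSpec(
            "spherical", 0.0, 2.0, 500.0)).fit(X, y).predict(pts)
        shifted = UniversalKriging(variogram=VariogramSpec(
            "spherical", 0.0, 2.0, 500.0)).fit(X, y + 7.5).predict(pts)
        assert np.allclose(shifted, base + 7.5, atol=1e-8)

    def test_duplicate_coordinates_rejected(self):
        X = np.array([[0, 0], [0, 0], [1, 1], [2, 2]], dtype=float)
        with pytest.raises(ValueError, match="duplicate"):
            UniversalKriging().fit(X, np.arange(4.0))

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            UniversalKriging().fit(np.array([[0, 0], [1, 1], [2, 0]]),
                                   np.arange(3.0))

    def test_cross_validation_error_shrinks_with_density(self):
        # leave-one-out error on a smooth field: denser networks do better
        rng = np.random.default_rng(12)

        def loo_rmse(n):
            X = rng.uniform(0, 3000, (n, 2))
            y = 10 + 3 * np.sin(X[:, 0] / 900) * np.cos(X[:, 1] / 900)
            errs = []
            for i in range(n):
                keep = np.arange(n) != i
                uk = UniversalKriging(nugget=0.0).fit(X[keep], y[keep])
                errs.append(uk.predict(X[i:i + 1])[0] - y[i])
            return float(np.sqrt(np.mean(np.square(errs))))

        assert loo_rmse(40) < loo_rmse(8)

    def test_krige_hour_from_station_records(self):
        spec = synth.StationSpec(noise_std=0.0, seed=3)
        stations = synth.generate_station_series(spec, n_days=2)
        values = [s.series.iloc[14] for s in stations]
        like = RasterGrid(values=np.zeros((12, 12)), origin=(748000, 9815000),
                          pixel_size=1200.0)
        out = krige_hour(stations, values, like)
        assert out.shape == (12, 12)
        assert np.all(np.isfinite(out.values))
        assert out.values.min() >= min(values) - 5
        assert out.values.max() <= max(values) + 5


class TestMonthlyMeans:
    def grid(self, value):
        return RasterGrid(values=np.full((4, 4), float(value)),
                          origin=(0, 120), pixel_size=30.0)

    def test_constant_month(self):
        surfaces = {1: [self.grid(10.0)] * 24}
        monthly, clim = monthly_mean_series(surfaces)
        assert monthly.loc[1, "mean_c"] == pytest.approx(10.0)
        assert monthly.loc[1, "complete"]
        assert np.allclose(clim.values, 10.0)

    def test_two_half_periods_average(self):
        surfaces = {1: [self.grid(8.0)] * 12 + [self.grid(12.0)] * 12}
        monthly, _ = monthly_mean_series(surfaces)
        assert monthly.loc[1, "mean_c"] == pytest.approx(10.0)

    def test_incomplete_month_flagged(self):
        surfaces = {1: [self.grid(10.0)] * 23}
        monthly, _ = monthly_mean_series(surfaces)
        assert not monthly.loc[1, "complete"]

    def test_sinusoidal_hours_match_analytic_mean(self):
        hours = np.arange(24)
        temps = 11.0 + 5.0 * np.cos(2 * np.pi * (hours - 14) / 24)
        surfaces = {1: [self.grid(t) for t in temps]}
        monthly, clim = monthly_mean_series(surfaces)
        # discrete mean of a full-period sampled cosine is exactly the offset
        assert monthly.loc[1, "mean_c"] == pytest.approx(11.0, abs=1e-9)
        assert clim.idxmax() == 14


class TestStationIO:
    def test_roundtrip(self, tmp_path):
        stations = synth.generate_station_series(synth.StationSpec(seed=1), 2)
        path = tmp_path / "stations.csv"
        write_stations_csv(stations, path)
        back = read_stations_csv(path)
        assert len(back) == len(stations)
        for a, b in zip(back, stations):
            assert a.station_id == b.station_id
            assert a.altitude == pytest.approx(b.altitude)
            assert np.allclose(a.series.values, b.series.values)
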