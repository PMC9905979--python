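import datetime as dt

import numpy as np
import pandas as pd
import pytest

from migradecide.geo import haversine_km
from migradecide.solar import sunset_utc
from migradecide.synthetic_world import SimConfig, simulate_weather
from migradecide.weather_annotation import (
    build_departure_table,
    build_flight_covariates,
    nearest_rain,
    sample_grid,
    standardize,
    unstandardize,
)


@pytest.fixture(scope="module")
def world():
    return simulate_weather(SimConfig(seed=42))


class TestSampleGrid:
    def test_cell_centre_returns_cell_value(self, world):
        lat, lon = world.lats[3], world.lons[4]
        when = world.times[10]
        s = sample_grid(world, lat, lon, when)
        assert s["u10"] == world.fields["u10"][10, 3, 4]

    def test_agrees_with_nearest_cell_oracle(self, world):
        rng = np.random.default_rng(0)
        for _ in range(100):
            lat = rng.uniform(world.lats[0], world.lats[-1])
            lon = rng.uniform(world.lons[0], world.lons[-1])
            it = int(rng.integers(0, len(world.times)))
            s = sample_grid(world, lat, lon, world.times[it])
            ilat = int(np.argmin([abs(la - lat) for la in world.lats]))
            ilon = int(np.argmin([abs(lo - lon) for lo in world.lons]))
            assert s["tcc"] == world.fields["tcc"][it, ilat, ilon]

    def test_outside_grid_rejected(self, world):
        with pytest.raises(ValueError):
            sample_grid(world, 80.0, 8.0, world.times[0])

    def test_outside_time_range_rejected(self, world):
        before = world.times[0] - np.timedelta64(1, "h")
        with pytest.raises(ValueError):
            sample_grid(world, world.lats[0], world.lons[0], before)


class TestNearestRain:
    def test_nearby_station_value(self, world):
        st = world.stations.iloc[0]
        when = world.times[5]
        val = nearest_rain(world, st["lat"], st["lon"], when)
        assert val == world.station_rain(0, when)

    def test_beyond_limit_is_missing(self, world):
        # a point in the grid's far corner, away from all stations
        lat, lon = world.lats[0], world.lons[0]
        d = min(
            haversine_km(lat, lon, s["lat"], s["lon"])
            for _, s in world.stations.iterrows()
        )
        if d < 20:
            pytest.skip("random station landed near the corner")
        assert nearest_rain(world, lat, lon, world.times[0]) is None

    def test_tie_breaks_to_lower_station_id(self, world):
        import copy

        w = copy.copy(world)
        w.stations = pd.DataFrame({
            "station_id": ["S01", "S00"],
            "lat": [54.0, 54.0],
            "lon": [8.0, 8.0],
        })
        w.rain = np.zeros((len(w.times), 2), dtype=np.int8)
        w.rain[:, 1] = 1  # S00 always raining
        assert nearest_rain(w, 54.0, 8.0, w.times[0]) == 1


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({"x": rng.normal(3, 7, 200)})
        out, scaling = standardize(df, ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        assert "x" in scaling

    def test_constant_column_errors_with_name(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df, ["flat"])

    def test_round_trip(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=50), "y": rng.uniform(0, 9, 50)})
        out, scaling = standardize(df, ["x", "y"])
        back = unstandardize(out, scaling)
        pd.testing.assert_frame_equal(back, df)


def _flights_frame(rows):
    return pd.DataFrame(rows)


class TestDepartureTable:
    def _mk(self, world, capture, begin, tag="b1"):
        lat, lon = 54.53, 8.88
        stopovers = pd.DataFrame([{
            "tag_id": tag, "capture_ts": pd.Timestamp(capture),
            "begin_ts": pd.Timestamp(begin), "min_stopover_days": 0,
        }])
        flights = pd.DataFrame([{
            "tag_id": tag, "species": "garden_warbler",
            "begin_ts": pd.Timestamp(begin), "begin_lat": lat,
            "begin_lon": lon, "end_ts": pd.Timestamp(begin),
            "end_lat": lat, "end_lon": lon, "route": "onshore", "landed": 0,
        }])
        return build_departure_table(stopovers, flights, world)

    def test_first_night_departure_single_row(self, world):
        tab = self._mk(world, "2021-08-20T09:00Z", "2021-08-20T21:30Z")
        assert len(tab) == 1
        assert tab["event"].tolist() == [1]

    def test_nine_night_stopover_gives_nine_rows(self, world):
        tab = self._mk(world, "2021-08-20T09:00Z", "2021-08-28T21:30Z")
        assert len(tab) == 9
        assert tab["event"].tolist() == [0] * 8 + [1]
        assert tab["night"].tolist() == list(range(1, 10))

    def test_rows_sampled_at_rounded_sunset(self, world):
        tab = self._mk(world, "2021-08-20T09:00Z", "2021-08-22T21:30Z")
        expected = sunset_utc(54.53, 8.88, dt.date(2021, 8, 21))
        assert tab.loc[tab["night"] == 2, "sunset"].iloc[0] == pd.Timestamp(expected)

    def test_constant_world_has_zero_deltas(self, world):
        import copy

        w = copy.copy(world)
        w.fields = {k: np.full_like(v, v.mean()) for k, v in world.fields.items()}
        tab = self._mk(w, "2021-08-20T09:00Z", "2021-08-25T21:30Z")
        for col in ("du24", "dv24", "dt24", "dp24"):
            assert (tab[col] == 0).all()

    def test_total_rows_equal_sum_of_nights(self, small_world, small_processed,
                                            small_tables):
        tab, _ = small_tables
        per_bird = tab.groupby("bird")["night"].max()
        assert len(tab) == per_bird.sum()

    def test_exactly_one_event_per_bird(self, small_tables):
        tab, _ = small_tables
        events = tab.groupby("bird")["event"].sum()
        assert (events == 1).all()


class TestFlightCovariates:
    def test_delta_consistency(self, small_tables):
        _, cov = small_tables
        assert np.allclose(cov["dv_flight"], cov["v_end"] - cov["v"])
        assert np.allclose(cov["du_flight"], cov["u_end"] - cov["u"])

    def test_one_row_per_flight(self, small_processed, small_tables):
        _, cov = small_tables
        assert len(cov) == len(small_processed["flights"])

    def test_offshore_indicator_matches_route(self, small_tables):
        _, cov = small_tables
        assert ((cov["route"] == "offshore") == (cov["offshore"] == 1)).all()
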