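import datetime as dt

import numpy as np
import pandas as pd
import pytest

from migradecide.geo import haversine_km
from migradecide.synthetic_world import (
    CAPTURE_SITES,
    SimConfig,
    build_receivers,
    simulate_decisions,
    simulate_detections,
    simulate_weather,
    simulate_world,
)
from migradecide.synthetic_world.decisions import (
    landing_probability,
    offshore_probability,
)

from .oracles import binomial_ci_halfwidth


class TestConfigValidation:
    def test_defaults_valid(self):
        SimConfig()

    def test_grid_step_must_be_quarter_degree(self):
        with pytest.raises(ValueError):
            SimConfig(grid_step=0.5)

    def test_burst_interval_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(burst_interval_range=(3.0, 8.0))

    def test_detection_radius_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(detection_radius_km=20.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(capture_start="08-31", capture_end="08-16")

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=5, detection_radius_km=6.5)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestWeather:
    def test_grid_spacing_exact(self):
        world = simulate_weather(SimConfig(seed=2))
        assert np.allclose(np.diff(world.lats), 0.25)
        assert np.allclose(np.diff(world.lons), 0.25)

    def test_fields_hourly_and_gap_free(self):
        world = simulate_weather(SimConfig(seed=2))
        assert (np.diff(world.times) == np.timedelta64(1, "h")).all()
        for arr in world.fields.values():
            assert np.isfinite(arr).all()

    def test_cloud_in_unit_interval(self):
        world = simulate_weather(SimConfig(seed=2))
        tcc = world.fields["tcc"]
        assert tcc.min() >= 0.0 and tcc.max() <= 1.0

    def test_ar_zero_gives_uncorrelated_u(self):
        world = simulate_weather(SimConfig(seed=3, wind_ar=0.0))
        u = world.fields["u10"][:, 0, 0]
        r = np.corrcoef(u[:-1], u[1:])[0, 1]
        assert abs(r) < 4.0 / np.sqrt(len(u))

    def test_rain_slope_zero_matches_base_rate(self):
        cfg = SimConfig(seed=4, rain_cloud_slope=0.0, rain_base_rate=0.2,
                        n_precip_stations=12)
        world = simulate_weather(cfg)
        rain = world.rain.ravel()
        n = rain.size
        assert n > 10_000
        assert abs(rain.mean() - 0.2) < binomial_ci_halfwidth(0.2, n)

    def test_pressure_within_bounds(self):
        cfg = SimConfig(seed=5)
        world = simulate_weather(cfg)
        sp = world.fields["sp"]
        slack = cfg.spatial_sd * 40 * 6  # static cell offsets
        assert sp.min() > cfg.pressure_mean - cfg.pressure_bound - slack
        assert sp.max() < cfg.pressure_mean + cfg.pressure_bound + slack

    def test_every_capture_site_has_station_within_20km(self):
        world = simulate_weather(SimConfig(seed=6))
        for lat, lon in CAPTURE_SITES.values():
            _, dist = world.nearest_station(lat, lon)
            assert dist < 20.0

    def test_same_seed_identical_fields(self):
        w1 = simulate_weather(SimConfig(seed=7))
        w2 = simulate_weather(SimConfig(seed=7))
        for name in w1.fields:
            assert np.array_equal(w1.fields[name], w2.fields[name])
        assert np.array_equal(w1.rain, w2.rain)


class TestDecisionModels:
    def test_offshore_probability_closed_form(self):
        cfg = SimConfig()
        # logistic(-2.16 - 1.40 * 2) for wind two s.d. eastward
        assert offshore_probability(cfg, 2.0) == pytest.approx(
            1.0 / (1.0 + np.exp(2.16 + 2.80)), rel=1e-12)
        assert offshore_probability(cfg, 2.0) == pytest.approx(0.00698, abs=2e-4)

    def test_landing_probability_at_zero_covariates(self):
        cfg = SimConfig()
        assert landing_probability(cfg, 0.0, 0.0) == pytest.approx(
            1.0 / (1.0 + np.exp(2.32)), rel=1e-12)
        assert landing_probability(cfg, 0.0, 0.0) == pytest.approx(0.0894, abs=2e-4)

    def test_zero_hazard_scale_means_no_departures(self):
        cfg = SimConfig(seed=8, baseline_rate=0.0,
                        n_birds={"garden_warbler": 15})
        world = simulate_weather(cfg)
        histories = simulate_decisions(world, cfg)
        assert all(h.departure_night is None for h in histories)

    def test_forced_onshore_species_never_offshore(self):
        cfg = SimConfig(seed=9, n_birds={"sedge_warbler": 40})
        world = simulate_weather(cfg)
        histories = simulate_decisions(world, cfg)
        assert all(h.route in (None, "onshore") for h in histories)

    def test_departure_after_capture_landing_after_departure(self):
        cfg = SimConfig(seed=10, n_birds={"garden_warbler": 30})
        world = simulate_weather(cfg)
        for h in simulate_decisions(world, cfg):
            if h.departure_ts is not None:
                assert h.departure_ts > h.capture_ts
                assert h.flight_end_ts > h.departure_ts

    def test_routing_logit_generative_consistency(self):
        """Realized offshore fraction matches the analytic expectation of
        the routing logit within Monte-Carlo error at large n."""
        rng = np.random.default_rng(11)
        cfg = SimConfig()
        z = rng.standard_normal(4000)
        p = 1.0 / (1.0 + np.exp(2.16 + 1.40 * z))
        draws = rng.random(4000) < p
        expect = p.mean()
        se = np.sqrt(np.var(p.mean() - p) / 4000 + expect * (1 - expect) / 4000)
        assert abs(draws.mean() - expect) < 2.5 * se


class TestDetections:
    def test_no_receiver_in_range_zero_true_detections(self):
        cfg = SimConfig(seed=12, n_birds={"garden_warbler": 5},
                        false_positive_rate=0.0)
        world = simulate_weather(cfg)
        histories = simulate_decisions(world, cfg)
        # receivers far outside the study area
        receivers = pd.DataFrame({
            "receiver_id": ["FAR"], "lat": [40.0], "lon": [-3.0],
            "is_coastal": [False], "is_helgoland_like": [False],
        })
        det = simulate_detections(histories, receivers, cfg)
        assert det.empty

    def test_detections_reference_known_receivers(self, small_world):
        det = small_world["detections"]
        known = set(small_world["receivers"]["receiver_id"])
        assert set(det["receiver_id"]) <= known

    def test_sorted_by_time(self, small_world):
        det = small_world["detections"]
        assert det["timestamp"].is_monotonic_increasing

    def test_false_positive_count_near_poisson_mean(self):
        cfg = SimConfig(seed=13, n_birds={"garden_warbler": 4},
                        false_positive_rate=0.05, detection_prob=0.0,
                        stopover_detection_prob=0.0)
        world = simulate_weather(cfg)
        histories = simulate_decisions(world, cfg)
        receivers = build_receivers(cfg)
        det = simulate_detections(histories, receivers, cfg)
        # all detections are false positives (detection probs zero)
        t_lo = min(h.capture_ts for h in histories)
        t_hi = max((h.flight_end_ts or h.censor_ts) for h in histories)
        span_h = (t_hi + dt.timedelta(days=1) - t_lo).total_seconds() / 3600
        lam = 0.05 * span_h * len(receivers)
        assert abs(len(det) - lam) < 4.0 * np.sqrt(lam)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=14, n_birds={"garden_warbler": 8})
        d1 = simulate_world(cfg)["detections"]
        d2 = simulate_world(cfg)["detections"]
        pd.testing.assert_frame_equal(d1, d2)


class TestIO:
    def test_write_read_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=15, n_birds={"garden_warbler": 6})
        res = simulate_world(cfg, out_dir=tmp_path)
        from migradecide.synthetic_world.io import read_world

        back = read_world(tmp_path)
        assert len(back["detections"]) == len(res["detections"])
        w1, w2 = res["world"], back["world"]
        assert np.array_equal(w1.rain, w2.rain)
        assert np.allclose(w1.fields["u10"], w2.fields["u10"], atol=1e-4)
        assert list(back["truth"]["tag_id"]) == list(res["truth"]["tag_id"])

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SimConfig(seed=16, n_birds={"garden_warbler": 6})
        simulate_world(cfg, out_dir=tmp_path / "a")
        simulate_world(cfg, out_dir=tmp_path / "b")
        for name in ("detections.csv", "weather.csv", "truth.csv",
                     "deployments.csv", "receivers.csv", "precip.csv"):
            a = (tmp_path / "a" / name).read_bytes()
            b = (tmp_path / "b" / name).read_bytes()
            assert a == b, name
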