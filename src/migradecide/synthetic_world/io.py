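"""Plain-text serialization of the synthetic world and a one-call driver."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .decisions import make_deployments, simulate_decisions, truth_frame
from .detections import simulate_detections
from .network import CAPTURE_SITES, build_receivers
from .weather import FIELDS, WeatherWorld, simulate_weather


def simulate_world(config: SimConfig, out_dir=None) -> dict:
    """Run the full generator; optionally write all outputs under out_dir.

    Returns a dict with keys ``config, world, receivers, deployments,
    histories, detections, truth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    world = simulate_weather(config)
    receivers = build_receivers(config)
    deployments = make_deployments(config, rng)
    histories = simulate_decisions(world, config, deployments=deployments, rng=rng)
    detections = simulate_detections(histories, receivers, config, world=world)
    truth = truth_frame(histories)
    result = {
        "config": config,
        "world": world,
        "receivers": receivers,
        "deployments": deployments,
        "histories": histories,
        "detections": detections,
        "truth": truth,
    }
    if out_dir is not None:
        write_world(result, out_dir)
    return result


def deployments_frame(deployments) -> pd.DataFrame:
    rows = []
    for d in deployments:
        lat, lon = CAPTURE_SITES[d["site"]]
        rows.append({
            "tag_id": d["tag_id"],
            "species": d["species"],
            "capture_ts": d["capture_ts"].isoformat(),
            "capture_lat": lat,
            "capture_lon": lon,
            "site": d["site"],
            "burst_interval": d["burst_interval"],
        })
    return pd.DataFrame(rows)


def weather_frame(world: WeatherWorld) -> pd.DataFrame:
    """Long-format hourly grid table (one row per cell-hour)."""
    tt, la, lo = np.meshgrid(world.times, world.lats, world.lons, indexing="ij")
    data = {"time": tt.ravel(), "lat": la.ravel(), "lon": lo.ravel()}
    for name in FIELDS:
        data[name] = world.fields[name].ravel()
    return pd.DataFrame(data)


def write_world(result: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["config"].to_yaml(out / "config.yaml")
    result["receivers"].to_csv(out / "receivers.csv", index=False)
    deployments_frame(result["deployments"]).to_csv(out / "deployments.csv", index=False)
    det = result["detections"].copy()
    det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00")
    det.to_csv(out / "detections.csv", index=False)
    weather_frame(result["world"]).to_csv(out / "weather.csv", index=False,
                                          float_format="%.4f")
    world = result["world"]
    world.stations.to_csv(out / "precip_stations.csv", index=False)
    rain_long = pd.DataFrame({
        "station_id": np.repeat(world.stations["station_id"].to_numpy(),
                                len(world.times)),
        "hour": np.tile(world.times, len(world.stations)),
        "rain": world.rain.T.ravel(),
    })
    rain_long.to_csv(out / "precip.csv", index=False)
    result["truth"].to_csv(out / "truth.csv", index=False)


def read_weather_csv(weather_path, stations_path=None, precip_path=None) -> WeatherWorld:
    df = pd.read_csv(weather_path, parse_dates=["time"])
    times = np.sort(df["time"].unique()).astype("datetime64[h]")
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    fields = {}
    df = df.sort_values(["time", "lat", "lon"], kind="mergesort")
    shape = (len(times), len(lats), len(lons))
    if len(df) != np.prod(shape):
        raise ValueError("weather table is not a full time x lat x lon grid")
    for name in FIELDS:
        fields[name] = df[name].to_numpy().reshape(shape)
    stations = pd.read_csv(stations_path) if stations_path else pd.DataFrame(
        columns=["station_id", "lat", "lon"])
    world = WeatherWorld(times=times, lats=lats, lons=lons, fields=fields,
                         stations=stations)
    if precip_path:
        rain = pd.read_csv(precip_path, parse_dates=["hour"])
        rain = rain.sort_values(["station_id", "hour"], kind="mergesort")
        world.rain = (
            rain["rain"].to_numpy()
            .reshape(len(stations), len(times)).T.astype(np.int8)
        )
    return world


def read_world(in_dir) -> dict:
    """Read back everything written by :func:`write_world`."""
    src = Path(in_dir)
    config = SimConfig.from_yaml(src / "config.yaml")
    receivers = pd.read_csv(src / "receivers.csv")
    deployments = pd.read_csv(src / "deployments.csv",
                              parse_dates=["capture_ts"])
    detections = pd.read_csv(src / "detections.csv", parse_dates=["timestamp"])
    world = read_weather_csv(src / "weather.csv", src / "precip_stations.csv",
                             src / "precip.csv")
    truth = pd.read_csv(src / "truth.csv")
    return {
        "config": config,
        "receivers": receivers,
        "deployments": deployments,
        "detections": detections,
        "world": world,
        "truth": truth,
    }
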