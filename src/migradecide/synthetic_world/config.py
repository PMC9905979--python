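"""Simulation configuration."""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import yaml


def _default_n_birds():
    return {"garden_warbler": 40, "greater_whitethroat": 40, "sedge_warbler": 40}


def _default_departure_coefs():
    # Standardized-scale generator coefficients for the nightly departure
    # hazard.  Change/cloud/rain/species values follow the fitted estimates
    # used as generator defaults; the wind curvature terms are kept moderate
    # so the hazard stays well behaved under N(0,1) covariates.
    return {
        "u_lin": -0.40,
        "u_quad": -0.30,
        "v_lin": -0.20,
        "v_quad": -0.15,
        "du24": -0.34,
        "dv24": -0.16,
        "dp24": 0.13,
        "cloud": -0.20,
        "rain": -0.74,
        "species[greater_whitethroat]": -0.02,
        "species[greater_whitethroat]:dp24": 0.35,
        "species[sedge_warbler]": -0.58,
        "species[sedge_warbler]:dp24": 0.05,
    }


def _default_routing_coefs():
    return {"intercept": -2.16, "u": -1.40}


def _default_landing_coefs():
    return {"intercept": -2.32, "dv_flight": 0.66, "cloud": 0.56}


def _default_standardization():
    # Fixed centre/scale pairs used by the generator so that its coefficient
    # vectors act on an N(0,1)-like scale; the fitting stage re-standardizes
    # from the realized sample.
    return {
        "u": (2.0, 3.0),
        "v": (0.0, 3.0),
        "du24": (0.0, 2.2),
        "dv24": (0.0, 2.2),
        "dp24": (0.0, 250.0),
        "cloud": (0.55, 0.25),
        "dv_flight": (0.0, 2.2),
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic world; ``seed`` fixes every output."""

    seed: int = 0
    n_birds: dict = field(default_factory=_default_n_birds)
    year: int = 2021
    capture_start: str = "08-16"           # month-day within `year`
    capture_end: str = "08-31"
    bbox: tuple = (53.0, 55.5, 6.0, 9.5)   # lat_min, lat_max, lon_min, lon_max
    grid_step: float = 0.25
    n_receivers: int = 12
    detection_radius_km: float = 8.0
    burst_interval_range: tuple = (4.5, 8.0)
    detection_prob: float = 0.5
    burst_stride: int = 10                 # emit every n-th burst in flight
    false_positive_rate: float = 0.02      # per receiver-hour
    airspeed_ms: float = 10.0
    wind_drift: bool = False
    max_nights: int = 20
    baseline_rate: float = 0.12            # nightly departure baseline hazard
    departure_coefs: dict = field(default_factory=_default_departure_coefs)
    routing_coefs: dict = field(default_factory=_default_routing_coefs)
    landing_coefs: dict = field(default_factory=_default_landing_coefs)
    standardization: dict = field(default_factory=_default_standardization)
    forced_onshore_species: tuple = ("sedge_warbler",)
    departure_offset_onshore: tuple = (1.9, 1.2)   # h after sunset, mean/sd
    departure_offset_offshore: tuple = (1.4, 0.8)
    landing_dwell_hours: float = 6.0
    stopover_beacon_hour: int = 10         # UTC hour of daily stopover beacon
    stopover_beacon_bursts: int = 5
    stopover_detection_prob: float = 0.9
    # weather process
    u_mean: float = 2.0
    u_sd: float = 3.0
    v_mean: float = 0.0
    v_sd: float = 3.0
    wind_ar: float = 0.85                  # hourly lag-1 autocorrelation
    temp_mean: float = 288.0
    temp_sd: float = 2.5
    temp_ar: float = 0.97
    pressure_mean: float = 101325.0
    pressure_bound: float = 1500.0
    pressure_step_sd: float = 40.0
    cloud_ar: float = 0.95
    cloud_bias: float = 0.3
    cloud_scale: float = 1.5
    rain_base_rate: float = 0.2
    rain_cloud_slope: float = 2.0
    n_precip_stations: int = 6
    spatial_sd: float = 0.5                # static cell-to-cell field offsets

    def __post_init__(self):
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_max > lat_min and lon_max > lon_min):
            raise ValueError("empty bounding box")
        if self.grid_step != 0.25:
            raise ValueError("grid spacing must be exactly 0.25 degrees")
        lo, hi = self.burst_interval_range
        if not (4.5 <= lo <= hi <= 8.0):
            raise ValueError("burst interval range must sit within [4.5, 8] s")
        if not (5.0 <= self.detection_radius_km <= 15.0):
            raise ValueError("detection radius must lie within [5, 15] km")
        if self.capture_date_start >= self.capture_date_end:
            raise ValueError("empty capture window")

    @property
    def capture_date_start(self) -> dt.date:
        m, d = (int(x) for x in self.capture_start.split("-"))
        return dt.date(self.year, m, d)

    @property
    def capture_date_end(self) -> dt.date:
        m, d = (int(x) for x in self.capture_end.split("-"))
        return dt.date(self.year, m, d)

    @property
    def species(self) -> list:
        return list(self.n_birds)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["bbox"] = list(data["bbox"])
        data["burst_interval_range"] = list(data["burst_interval_range"])
        data["forced_onshore_species"] = list(data["forced_onshore_species"])
        data["departure_offset_onshore"] = list(data["departure_offset_onshore"])
        data["departure_offset_offshore"] = list(data["departure_offset_offshore"])
        data["standardization"] = {k: list(v) for k, v in data["standardization"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("bbox", "burst_interval_range", "forced_onshore_species",
                    "departure_offset_onshore", "departure_offset_offshore"):
            if key in data:
                data[key] = tuple(data[key])
        if "standardization" in data:
            data["standardization"] = {
                k: tuple(v) for k, v in data["standardization"].items()
            }
        return cls(**data)
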