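import numpy as np
import pandas as pd
import pytest

from migradecide.synthetic_world import SimConfig, simulate_world
from migradecide.synthetic_world.io import deployments_frame


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=11,
        n_birds={"garden_warbler": 25, "greater_whitethroat": 25,
                 "sedge_warbler": 25},
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """One modest synthetic world shared by read-only tests."""
    return simulate_world(small_config)


@pytest.fixture(scope="session")
def small_deployments(small_world):
    dep = deployments_frame(small_world["deployments"])
    dep["capture_ts"] = pd.to_datetime(dep["capture_ts"])
    return dep


@pytest.fixture(scope="session")
def small_processed(small_world, small_deployments):
    from migradecide.track_processing import process_tracks

    return process_tracks(small_world["detections"], small_world["receivers"],
                          small_deployments)


@pytest.fixture(scope="session")
def small_tables(small_world, small_processed):
    from migradecide.weather_annotation import (
        build_departure_table,
        build_flight_covariates,
    )

    dep = build_departure_table(small_processed["stopovers"],
                                small_processed["flights"],
                                small_world["world"])
    cov = build_flight_covariates(small_processed["flights"],
                                  small_processed["stopovers"],
                                  small_world["world"])
    return dep, cov


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
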