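import numpy as np
import pandas as pd
import pytest

from plastrend.censoring import impute_table
from plastrend.spatial_reference import (
    BasinPolygons,
    attach_spatial,
    scale_center_by_basin,
)
from plastrend.station_io import add_concentrations, filter_mesh, read_stations
from plastrend.synthetic_data import (
    SimulationConfig,
    simulate_campaign,
    synthetic_expected_field,
)
from plastrend.wind_correction import correct_table


@pytest.fixture(scope="session")
def polygons():
    return BasinPolygons.default()


@pytest.fixture(scope="session")
def field():
    """The packaged synthetic expected field, z-scored per basin."""
    return scale_center_by_basin(synthetic_expected_field())


@pytest.fixture(scope="session")
def campaign():
    """One default synthetic campaign (stations + per-station truth)."""
    cfg = SimulationConfig(seed=7)
    stations, truth = simulate_campaign(cfg)
    return cfg, stations, truth


def process_stations(stations: pd.DataFrame, field, polygons, tmp_path):
    """Run ingest -> wind -> basin -> impute on an in-memory station table."""
    path = tmp_path / "stations.csv"
    stations.to_csv(path, index=False)
    df = read_stations(path)
    df, _ = filter_mesh(df)
    df = add_concentrations(df)
    df = correct_table(df)
    df = attach_spatial(df, field, polygons)
    df, _ = impute_table(df)
    return df


@pytest.fixture(scope="session")
def processed(campaign, field, polygons, tmp_path_factory):
    """Default campaign carried through every pre-model stage."""
    _, stations, _ = campaign
    return process_stations(stations, field, polygons,
                            tmp_path_factory.mktemp("proc"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
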