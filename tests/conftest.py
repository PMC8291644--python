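import numpy as np
import pandas as pd
import pytest

from droughtgam import (
    GridConfig,
    SimulationConfig,
    attach_exposure,
    generate_population,
    generate_rainfall_grid,
)


@pytest.fixture(scope="session")
def small_grid():
    """25-year, 5x5-degree grid at 1-degree resolution."""
    return generate_rainfall_grid(
        GridConfig(lat_min=0, lat_max=5, lon_min=0, lon_max=5, resolution_deg=1.0,
                   n_years=25, seed=11)
    )


@pytest.fixture(scope="session")
def study_grid():
    """Denser 30-year grid matching the simulation-study defaults."""
    return generate_rainfall_grid(
        GridConfig(lat_min=0, lat_max=10, lon_min=0, lon_max=10, resolution_deg=0.5,
                   n_years=30, seed=7)
    )


@pytest.fixture(scope="session")
def population(study_grid):
    """~1,200 women in 60 clusters with exposure columns attached."""
    cfg = SimulationConfig(
        n_surveys=3, n_clusters_per_survey=20, n_women_per_cluster=20,
        beta0=-1.0, spatial_sd=0.8, spatial_range_km=300.0,
        survey_effects=[0.0, 0.2, -0.2], seed=42,
    )
    pop = generate_population(cfg, study_grid)
    return attach_exposure(pop, study_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_coords(rng, n, lat_span=5.0, lon_span=5.0):
    return np.column_stack([rng.uniform(0, lat_span, n), rng.uniform(0, lon_span, n)])
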