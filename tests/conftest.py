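import pytest

from aqburden import (
    GridSpec,
    SyntheticScenario,
    assign_countries,
    assign_exposure,
    generate_grid,
    generate_mortality_rates,
    generate_population,
    generate_small_areas,
    simulate_exposure,
    weights_from_cell_assignment,
)
from aqburden.reporting import run_pipeline

#: Scaled-down study configuration reused across tests (3 years, 60 areas).
MINI_CONFIG = {
    "grid": {"n_cols": 20, "n_rows": 30, "cell_size": 1000.0},
    "scenario": {"years": (2008, 2010)},
    "areas": {"n_areas": 60},
    "uncertainty": {"n_draws": 200},
}


@pytest.fixture(scope="session")
def mini_run():
    """One full pipeline execution shared by read-only tests."""
    return run_pipeline(MINI_CONFIG, seed=7)


@pytest.fixture(scope="session")
def fixture50():
    """Seeded 50-area, 19-band, 2-year stack of study inputs."""
    grid = generate_grid(GridSpec(10, 10))
    scenario = SyntheticScenario(years=(2008, 2009), n_hotspots=2, seed=11)
    countries = assign_countries(grid, scenario)
    areas, assignment = generate_small_areas(
        grid, 50, seed=11, countries=countries
    )
    x = assign_exposure(
        weights_from_cell_assignment(assignment), simulate_exposure(grid, scenario)
    )
    pop = generate_population(areas, seed=11)
    rates = generate_mortality_rates(sorted(areas["region"].unique()), seed=11)
    return {"grid": grid, "areas": areas, "assignment": assignment,
            "x": x, "pop": pop, "rates": rates}
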