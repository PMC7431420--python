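import pandas as pd
import pytest

from plovernet import analyses, synthetic
from plovernet.config import PopulationConfig


@pytest.fixture(scope="session")
def small_config() -> PopulationConfig:
    return PopulationConfig(n_individuals=60, n_years=3, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config) -> synthetic.SimulatedData:
    return synthetic.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_sim) -> analyses.DataBundle:
    return analyses.build_bundle(small_sim.sightings, small_sim.nests)


@pytest.fixture(scope="session")
def default_sim() -> synthetic.SimulatedData:
    """Dataset at the generator's default study conditions."""
    return synthetic.simulate_dataset(PopulationConfig(seed=5))


@pytest.fixture(scope="session")
def default_bundle(default_sim) -> analyses.DataBundle:
    return analyses.build_bundle(default_sim.sightings, default_sim.nests)


def make_period(ids_xy: dict[str, tuple[float, float]], period_id: str = "P1",
                year: int = 2015) -> pd.DataFrame:
    """Sightings table for one sampling period from an id -> (x, y) map."""
    rows = []
    for ind, (x, y) in ids_xy.items():
        rows.append(
            {
                "individual_id": ind,
                "sex": "M" if ind.startswith("M") else "F",
                "date": pd.Timestamp("2015-03-01"),
                "period_id": period_id,
                "x": float(x),
                "y": float(y),
                "habitat": "saltmarsh",
                "year": year,
            }
        )
    return pd.DataFrame(rows)
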